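"""Synthetic cohort generator: determinism, weight recovery, validation."""

import numpy as np
import pandas as pd
import pytest

from platemix.errors import ConfigError
from platemix.simulate import (
    GroupSpec,
    SimConfig,
    SurvivalSpec,
    default_study_config,
    simulate_beads,
    simulate_cohort,
    simulate_survival,
)


def _small_config(seed=0, **group_kwargs):
    g = GroupSpec("g", n_mice=2, events_per_mouse=2000, **group_kwargs)
    return SimConfig(groups=(g,), seed=seed)


class TestCohort:
    def test_bytewise_determinism(self):
        cfg = _small_config(seed=11)
        ev1, tr1 = simulate_cohort(cfg)
        ev2, tr2 = simulate_cohort(cfg)
        assert ev1.to_csv(index=False) == ev2.to_csv(index=False)
        assert tr1.mouse_weights.to_csv(index=False) == tr2.mouse_weights.to_csv(index=False)
        assert (tr1.event_labels == tr2.event_labels).all()

    def test_different_seeds_differ(self):
        ev1, _ = simulate_cohort(_small_config(seed=1))
        ev2, _ = simulate_cohort(_small_config(seed=2))
        assert not np.array_equal(ev1["fsc"].to_numpy(), ev2["fsc"].to_numpy())

    def test_label_fraction_matches_configured_weight(self):
        # jitter 0: pooled aggregate label fraction is binomial around 0.16.
        g = GroupSpec(
            "g", n_mice=7, events_per_mouse=10_000,
            level1_weight_aggregates=0.16, mouse_weight_jitter_sd=0.0,
        )
        _, truth = simulate_cohort(SimConfig(groups=(g,), seed=5))
        n = 7 * 10_000
        frac = (truth.event_labels == "aggregate").mean()
        se = np.sqrt(0.16 * 0.84 / n)
        assert abs(frac - 0.16) < 3 * se

    @pytest.mark.parametrize("n_events", [2_000, 8_000, 32_000])
    def test_fraction_error_shrinks_with_sample_size(self, n_events):
        g = GroupSpec(
            "g", n_mice=1, events_per_mouse=n_events,
            level1_weight_aggregates=0.16, mouse_weight_jitter_sd=0.0,
        )
        _, truth = simulate_cohort(SimConfig(groups=(g,), seed=3))
        frac = (truth.event_labels == "aggregate").mean()
        assert abs(frac - 0.16) < 4 * np.sqrt(0.16 * 0.84 / n_events)

    def test_aggregates_larger_than_normoplatelets_every_mouse(self):
        cfg = default_study_config(seed=4)
        events, truth = simulate_cohort(cfg)
        df = events.assign(label=truth.event_labels.values)
        for _, sub in df.groupby("mouse_id"):
            agg = sub.loc[sub["label"] == "aggregate", "fsc"].mean()
            normo = sub.loc[sub["label"] != "aggregate", "fsc"].mean()
            assert agg > normo

    def test_fsc_strictly_positive(self):
        ev, _ = simulate_cohort(_small_config(seed=9))
        assert (ev["fsc"] > 0).all()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(level1_weight_aggregates=0.0), "level1_weight_aggregates"),
            (dict(level1_weight_aggregates=1.0), "level1_weight_aggregates"),
            (dict(level2_weight_large=-0.1), "level2_weight_large"),
            (dict(mouse_weight_jitter_sd=-1.0), "mouse_weight_jitter_sd"),
            (
                dict(emg_params_per_class={
                    "small_normo": (185.0, -3.0, 1 / 42.0),
                    "large_normo": (435.0, 48.0, 1 / 58.0),
                    "aggregate": (1150.0, 140.0, 1 / 300.0),
                }),
                "sigma",
            ),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            simulate_cohort(_small_config(**kwargs))


class TestBeads:
    def test_noiseless_power_law_is_exact(self):
        cfg = SimConfig(
            groups=(GroupSpec("g"),), seed=0,
            bead_sizes_um=(1.0, 2.0, 4.0, 8.0, 15.0), bead_fsc_noise_cv=0.0,
        )
        beads = simulate_beads(cfg)
        expected = 100.0 * np.array([1, 2, 4, 8, 15.0]) ** 1.5
        np.testing.assert_allclose(beads["fsc"].to_numpy(), expected, rtol=1e-12)

    def test_same_seed_identical(self):
        cfg = SimConfig(groups=(GroupSpec("g"),), seed=21)
        assert simulate_beads(cfg).equals(simulate_beads(cfg))

    def test_noise_cv_realized(self):
        # 1000 replicate draws at one size: sample CV within 20% of nominal.
        draws = []
        for seed in range(1000):
            cfg = SimConfig(
                groups=(GroupSpec("g"),), seed=seed,
                bead_sizes_um=(1.0, 4.0, 15.0), bead_fsc_noise_cv=0.05,
            )
            draws.append(simulate_beads(cfg)["fsc"].iloc[1])
        draws = np.asarray(draws)
        cv = draws.std(ddof=1) / draws.mean()
        assert cv == pytest.approx(0.05, rel=0.20)

    def test_too_few_or_unsorted_sizes_rejected(self):
        with pytest.raises(ConfigError, match="bead_sizes_um"):
            SimConfig(groups=(GroupSpec("g"),), bead_sizes_um=(1.0, 2.0)).validate()
        with pytest.raises(ConfigError, match="bead_sizes_um"):
            SimConfig(groups=(GroupSpec("g"),), bead_sizes_um=(1.0, 3.0, 2.0)).validate()


class TestSurvival:
    def test_vanishing_hazard_censors_everyone(self):
        cfg = SimConfig(
            groups=(GroupSpec("g"),), seed=0,
            survival=(SurvivalSpec("a", 30, weibull_scale_days=1e9),
                      SurvivalSpec("b", 20, weibull_scale_days=1e9)),
        )
        surv = simulate_survival(cfg)
        assert (surv["event"] == 0).all()
        assert (surv["time_days"] == cfg.censor_horizon_days).all()

    def test_times_respect_horizon(self):
        cfg = default_study_config(seed=8)
        surv = simulate_survival(cfg)
        assert (surv["time_days"] <= cfg.censor_horizon_days).all()
        assert (surv["time_days"] > 0).all()
        assert surv.groupby("group").size().to_dict() == {"4T1": 80, "4T1+ASA/Cl": 40}

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ConfigError, match="weibull_scale_days"):
            SurvivalSpec("a", 10, weibull_scale_days=0.0).validate()
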