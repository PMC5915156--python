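"""Mann-Whitney U (exact + approximate), bootstrap boosting, Grubbs screening."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from platemix.errors import InputError
from platemix.resampling import (
    bootstrap_mw,
    grubbs_critical,
    grubbs_filter,
    mannwhitney_u,
)


def _enumerated_p(x, y, u_obs):
    """Brute-force one-sided p over all label assignments (untied data)."""
    allv = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n2):
        yy = allv[list(comb)]
        xx = np.delete(allv, list(comb))
        u = (yy[:, None] > xx[None, :]).sum()
        total += 1
        if u >= u_obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_textbook_separated_triplets(self):
        u, p, method = mannwhitney_u([1, 2, 3], [4, 5, 6], "greater")
        assert (u, p, method) == (9.0, 0.05, "exact")

    def test_all_tied_gives_half(self):
        u, p, method = mannwhitney_u([5, 5, 5], [5, 5, 5], "greater")
        assert u == 4.5
        assert p == 0.5

    @pytest.mark.parametrize("n1", [2, 3, 4, 5])
    @pytest.mark.parametrize("n2", [2, 3, 4, 5])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = vals[:n1], vals[n1:]
        u, p, method = mannwhitney_u(x, y, "greater")
        assert method == "exact"
        assert p == pytest.approx(_enumerated_p(x, y, u), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1.0, size=8)
        u, p, method = mannwhitney_u(x, y, "greater")
        ref = stats.mannwhitneyu(y, x, alternative="greater", method="exact")
        assert method == "exact"
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_asymptotic_for_large_n(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(0.5, size=25)
        u, p, method = mannwhitney_u(x, y, "greater")
        ref = stats.mannwhitneyu(
            y, x, alternative="greater", method="asymptotic", use_continuity=True
        )
        assert method == "normal-approx"
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=8),
        st.lists(st.integers(0, 30), min_size=2, max_size=8),
    )
    def test_antisymmetry_under_sample_swap(self, xs, ys):
        _, p1, _ = mannwhitney_u(xs, ys, "greater")
        _, p2, _ = mannwhitney_u(ys, xs, "less")
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mannwhitney_u([], [1.0])


class TestBootstrap:
    def test_complete_separation_closed_form(self):
        # Resampling preserves separation, so every bootstrap p is 1/C(14,7).
        res = bootstrap_mw(np.arange(1, 8), np.arange(8, 15), "greater", b=300, seed=0)
        assert res.p_median == pytest.approx(1 / 3432, abs=1e-15)
        assert res.p_ci == (pytest.approx(1 / 3432), pytest.approx(1 / 3432))
        assert res.prop_significant_at_0_05 == 1.0
        assert res.p_single == pytest.approx(1 / 3432)

    def test_identical_constant_samples_give_half(self):
        res = bootstrap_mw([5.0] * 5, [5.0] * 5, "greater", b=50, seed=0)
        assert res.p_median == 0.5
        assert res.p_single == 0.5

    def test_seed_reproducibility_and_cross_seed_stability(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 7)
        y = rng.normal(1.0, 1.0, 7)
        r1 = bootstrap_mw(x, y, "greater", b=1000, seed=1)
        r1b = bootstrap_mw(x, y, "greater", b=1000, seed=1)
        r2 = bootstrap_mw(x, y, "greater", b=1000, seed=2)
        assert r1 == r1b
        assert abs(r1.p_median - r2.p_median) < 0.02

    def test_bad_b_rejected(self):
        with pytest.raises(InputError):
            bootstrap_mw([1, 2, 3], [4, 5, 6], b=0)


class TestGrubbs:
    def test_worked_example_removes_single_outlier(self):
        res = grubbs_filter([1.0, 2.0, 3.0, 100.0], alpha=0.05)
        assert res.removed == (100.0,)
        assert res.g_statistics[0] == pytest.approx(1.4998, abs=1e-4)
        assert grubbs_critical(4, 0.05) == pytest.approx(1.4813, abs=1e-4)
        assert sorted(res.retained) == [1.0, 2.0, 3.0]

    def test_short_ramp_untouched(self):
        res = grubbs_filter([1, 2, 3, 4, 5])
        assert res.removed == ()
        assert len(res.retained) == 5

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(size=12), 8.0, -9.0]
        first = grubbs_filter(vals)
        second = grubbs_filter(first.retained)
        assert second.removed == ()

    def test_null_first_pass_removal_rate_near_alpha(self):
        # Type-I error calibration: Normal samples of size 10.
        rng = np.random.default_rng(77)
        removals = 0
        n_sim = 10_000
        for _ in range(n_sim):
            res = grubbs_filter(rng.normal(size=10), alpha=0.05)
            removals += len(res.removed) > 0
        assert removals / n_sim == pytest.approx(0.05, abs=0.02)

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            grubbs_filter([1.0, 2.0])

    def test_partition_preserved(self):
        vals = (1.0, 2.0, 3.0, 4.0, 50.0, -60.0)
        res = grubbs_filter(vals)
        assert sorted(res.retained + res.removed) == sorted(vals)
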