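"""Two-level decomposition of platelet FSC events, per mouse and per group.

Level 1 fits a 2-component EMG mixture to all of a mouse's gated events and
labels the higher-mean component "aggregates" (the lower-mean one
"normoplatelets"). Level 2 refits a 2-component mixture on the events
classified as normoplatelets and labels the higher-mean component "large"
platelets. Percentages are classified-event fractions (the per-object
reading of the figure legends); the fitted mixture weights are reported
alongside. When a bead calibration curve is supplied, each class's fitted
mean FSC is converted to an estimated size in micrometres.

Events are assumed already gated upstream on the platelet-specific antigen
CD41/61 — the pipeline consumes gated events only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, fsc_to_size
from .errors import ConfigError, DegenerateFitError, InputError
from .mixture import EMGMixture, MixtureFitResult, classify, fit_mixture, quantile_init
from .resampling import GroupComparisonResult, bootstrap_mw

__all__ = [
    "MouseSummary",
    "GroupSummary",
    "analyze_mouse",
    "summarize_group",
    "run_pipeline",
    "GROUP_METRICS",
]

# Separation (difference of component means over pooled within-component SD)
# below which a 2-component split is considered spurious.
_MIN_SEPARATION = 0.1

GROUP_METRICS = (
    "pct_aggregates",
    "pct_normoplatelets",
    "pct_large_normo",
    "pct_small_normo",
    "size_small_um",
    "size_large_um",
    "size_aggregates_um",
)


@dataclass
class MouseSummary:
    """Per-mouse subpopulation percentages, sizes and fit diagnostics."""

    mouse_id: str
    group: str
    n_events: int
    pct_aggregates: float
    pct_normoplatelets: float
    pct_large_normo: float  # % of normoplatelet events
    pct_small_normo: float
    weight_aggregates: float  # fitted level-1 mixture weight
    weight_large_normo: float
    n_normo_events: int
    level1_ok: bool
    level2_ok: bool
    level1_converged: bool
    level2_converged: bool
    loglik_level1: float
    loglik_level2: float
    size_small_um: float = math.nan
    size_large_um: float = math.nan
    size_aggregates_um: float = math.nan
    size_extrapolated: bool = False
    notes: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class GroupSummary:
    """Across-mouse median and IQR of one metric."""

    group: str
    metric: str
    n_mice: int
    median: float
    iqr_lower: float
    iqr_upper: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "metric": self.metric,
            "n_mice": self.n_mice,
            "median": self.median,
            "iqr": [self.iqr_lower, self.iqr_upper],
        }


def _separation(mix: EMGMixture) -> float:
    (m1, m2) = mix.means
    v = [c.sigma**2 + 1.0 / c.lam**2 for c in mix.components]
    pooled_sd = math.sqrt(0.5 * (v[0] + v[1]))
    return abs(m2 - m1) / pooled_sd if pooled_sd > 0 else 0.0


def _class_size(
    mean_fsc: float, curve: Optional[CalibrationCurve]
) -> Tuple[float, bool]:
    if curve is None or not np.isfinite(mean_fsc) or mean_fsc <= 0:
        return math.nan, False
    return fsc_to_size(mean_fsc, curve)


def analyze_mouse(
    events,
    mouse_id: str = "",
    group: str = "",
    calibration: Optional[CalibrationCurve] = None,
    seed: int = 0,
    level2_min_events: int = 50,
) -> MouseSummary:
    """Run the two-level decomposition on one mouse's FSC events.

    Requires >= 100 events. If the level-1 fit degenerates or the two fitted
    components are not meaningfully separated, the summary is flagged
    (``level1_ok`` False, percentages NaN) instead of reporting a spurious
    split. A level-2 refit is only attempted when at least
    ``level2_min_events`` events were classified as normoplatelets.
    """
    x = np.asarray(events, dtype=float).ravel()
    if x.size < 100:
        raise InputError(f"analyze_mouse needs >= 100 events, got {x.size}")

    nan = math.nan
    notes = []
    try:
        fit1 = fit_mixture(x, k=2, seed=seed)
    except DegenerateFitError as exc:
        return MouseSummary(
            mouse_id=mouse_id, group=group, n_events=int(x.size),
            pct_aggregates=nan, pct_normoplatelets=nan,
            pct_large_normo=nan, pct_small_normo=nan,
            weight_aggregates=nan, weight_large_normo=nan,
            n_normo_events=0, level1_ok=False, level2_ok=False,
            level1_converged=False, level2_converged=False,
            loglik_level1=nan, loglik_level2=nan,
            notes=f"level-1 degenerate: {exc}",
        )
    labels1, _ = classify(x, fit1.mixture)
    sep1 = _separation(fit1.mixture)
    level1_ok = fit1.converged and sep1 >= _MIN_SEPARATION
    if sep1 < _MIN_SEPARATION:
        notes.append(f"level-1 components nearly coincident (separation {sep1:.3g})")

    n_agg = int((labels1 == 1).sum())
    normo = x[labels1 == 0]
    pct_agg = 100.0 * n_agg / x.size if level1_ok else nan
    pct_normo = 100.0 - pct_agg if level1_ok else nan

    # Level 2: small vs large within normoplatelets.
    level2_ok = False
    level2_converged = False
    pct_large = pct_small = nan
    w_large = nan
    loglik2 = nan
    size_small = size_large = math.nan
    extrap = False
    if level1_ok and normo.size >= level2_min_events:
        try:
            # The large-platelet class is a ~7% minority of normoplatelets;
            # seed the refit with a quantile split matched to that prior,
            # which keeps EM out of the wrong local basin.
            fit2 = fit_mixture(
                normo,
                k=2,
                init=quantile_init(normo, 2, minority_weight=0.08),
                seed=seed + 1,
            )
            labels2, _ = classify(normo, fit2.mixture)
            sep2 = _separation(fit2.mixture)
            level2_converged = fit2.converged
            if fit2.converged and sep2 >= _MIN_SEPARATION:
                level2_ok = True
                n_large = int((labels2 == 1).sum())
                pct_large = 100.0 * n_large / normo.size
                pct_small = 100.0 - pct_large
                w_large = fit2.mixture.weights[1]
                loglik2 = fit2.loglik
                size_small, e1 = _class_size(fit2.mixture.means[0], calibration)
                size_large, e2 = _class_size(fit2.mixture.means[1], calibration)
                extrap = bool(e1 or e2)
            else:
                notes.append("level-2 split unreliable")
        except DegenerateFitError:
            notes.append("level-2 degenerate")
    elif level1_ok:
        notes.append(
            f"level-2 skipped: only {normo.size} normoplatelet events "
            f"(< {level2_min_events})"
        )

    size_agg, e3 = _class_size(
        fit1.mixture.means[1] if level1_ok else math.nan, calibration
    )
    extrap = bool(extrap or e3)

    return MouseSummary(
        mouse_id=mouse_id,
        group=group,
        n_events=int(x.size),
        pct_aggregates=pct_agg,
        pct_normoplatelets=pct_normo,
        pct_large_normo=pct_large,
        pct_small_normo=pct_small,
        weight_aggregates=fit1.mixture.weights[1] if level1_ok else nan,
        weight_large_normo=w_large,
        n_normo_events=int(normo.size),
        level1_ok=level1_ok,
        level2_ok=level2_ok,
        level1_converged=fit1.converged,
        level2_converged=level2_converged,
        loglik_level1=fit1.loglik,
        loglik_level2=loglik2,
        size_small_um=size_small,
        size_large_um=size_large,
        size_aggregates_um=size_agg,
        size_extrapolated=extrap,
        notes="; ".join(notes),
    )


def summarize_group(summaries: Sequence[MouseSummary], metric: str) -> GroupSummary:
    """Median and 25th/75th percentile (linear interpolation) across mice.

    No outlier removal happens here — Grubbs screening, where used, is an
    explicit separate step.
    """
    if len(summaries) < 2:
        raise InputError("summarize_group needs >= 2 mice")
    if metric not in GROUP_METRICS:
        raise InputError(f"unknown metric {metric!r}; choose from {GROUP_METRICS}")
    groups = {s.group for s in summaries}
    if len(groups) != 1:
        raise InputError(f"summaries span multiple groups: {sorted(groups)}")
    vals = np.asarray([getattr(s, metric) for s in summaries], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise InputError(f"metric {metric!r} has < 2 finite values")
    lo, med, hi = np.percentile(vals, [25.0, 50.0, 75.0])
    return GroupSummary(
        group=groups.pop(),
        metric=metric,
        n_mice=int(vals.size),
        median=float(med),
        iqr_lower=float(lo),
        iqr_upper=float(hi),
    )


_DEFAULT_COMPARISONS = (
    # (metric, alternative for "treated vs control"): the treatment is
    # expected to lower the aggregate share and raise the large-platelet
    # share.
    ("pct_aggregates", "less"),
    ("pct_large_normo", "greater"),
)


def run_pipeline(
    events: pd.DataFrame,
    beads: Optional[pd.DataFrame] = None,
    comparisons: Optional[Sequence[Tuple[str, str]]] = _DEFAULT_COMPARISONS,
    control_group: Optional[str] = None,
    pooled: bool = False,
    bootstrap_b: int = 1000,
    seed: int = 0,
) -> dict:
    """Full analysis: per-mouse decomposition, group summaries, comparisons.

    Parameters
    ----------
    events : DataFrame with columns (mouse_id, group, fsc).
    beads : optional bead table (size_um, fsc) for size calibration.
    comparisons : sequence of (metric, alternative) pairs, tested with the
        bootstrap-boosted one-sided Mann-Whitney U (treated arm as ``y``
        against the control arm as ``x``); pass None or () for summaries
        only. Requires exactly two groups when non-empty.
    control_group : which group plays the reference role in comparisons;
        defaults to the lexicographically first group label.
    pooled : additionally fit the mixtures on all events of each group
        concatenated and report the pooled classified fractions (the
        "overall population" reading of the analysis).
    bootstrap_b : bootstrap iterations per comparison (the study used 1000).
    seed : seeds all EM restarts and bootstrap draws.
    """
    required = {"mouse_id", "group", "fsc"}
    if not required.issubset(events.columns):
        raise InputError(f"events needs columns {sorted(required)}")
    curve = None
    if beads is not None:
        from .calibration import fit_bead_curve

        curve = fit_bead_curve(beads)

    group_of_mouse = events.groupby("mouse_id")["group"].nunique()
    if (group_of_mouse > 1).any():
        bad = group_of_mouse[group_of_mouse > 1].index.tolist()
        raise InputError(f"mice assigned to multiple groups: {bad}")

    groups = sorted(events["group"].unique())
    if comparisons and len(groups) != 2:
        raise ConfigError(
            f"comparisons require exactly 2 groups, got {len(groups)}: {groups}"
        )

    summaries: List[MouseSummary] = []
    for i, (mouse_id, sub) in enumerate(sorted(events.groupby("mouse_id"))):
        summaries.append(
            analyze_mouse(
                sub["fsc"].to_numpy(),
                mouse_id=str(mouse_id),
                group=str(sub["group"].iloc[0]),
                calibration=curve,
                seed=seed + 101 * i,
            )
        )

    group_summaries: Dict[str, List[GroupSummary]] = {}
    for grp in groups:
        grp_sums = [s for s in summaries if s.group == grp]
        out = []
        for metric in GROUP_METRICS:
            try:
                out.append(summarize_group(grp_sums, metric))
            except InputError:
                continue  # metric unavailable for this group (e.g. no beads)
        group_summaries[grp] = out

    comparison_results: Dict[str, GroupComparisonResult] = {}
    if comparisons:
        ctrl = control_group if control_group is not None else groups[0]
        if ctrl not in groups:
            raise ConfigError(f"control_group {ctrl!r} not among groups {groups}")
        other = [g for g in groups if g != ctrl][0]
        for j, (metric, alternative) in enumerate(comparisons):
            xs = [getattr(s, metric) for s in summaries if s.group == ctrl]
            ys = [getattr(s, metric) for s in summaries if s.group == other]
            xs = [v for v in xs if np.isfinite(v)]
            ys = [v for v in ys if np.isfinite(v)]
            comparison_results[metric] = bootstrap_mw(
                xs, ys, alternative=alternative, b=bootstrap_b, seed=seed + 7919 * (j + 1)
            )

    pooled_results = {}
    if pooled:
        for grp in groups:
            x = events.loc[events["group"] == grp, "fsc"].to_numpy()
            fit1 = fit_mixture(x, k=2, seed=seed)
            labels1, _ = classify(x, fit1.mixture)
            normo = x[labels1 == 0]
            entry = {
                "pct_aggregates": 100.0 * float((labels1 == 1).mean()),
                "n_events": int(x.size),
                "level1_converged": fit1.converged,
            }
            if normo.size >= 50:
                fit2 = fit_mixture(normo, k=2, seed=seed + 1)
                labels2, _ = classify(normo, fit2.mixture)
                entry["pct_large_normo"] = 100.0 * float((labels2 == 1).mean())
                entry["level2_converged"] = fit2.converged
            pooled_results[grp] = entry

    report = {
        "seed": seed,
        "groups": groups,
        "calibration": curve.to_dict() if curve is not None else None,
        "mouse_summaries": [s.to_dict() for s in summaries],
        "group_summaries": {
            g: [gs.to_dict() for gs in lst] for g, lst in group_summaries.items()
        },
        "comparisons": {m: r.to_dict() for m, r in comparison_results.items()},
        "pooled": pooled_results or None,
    }
    return report
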