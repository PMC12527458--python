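"""IBDQ-anchored derivation of the MCS score table.

The scoring rule behind the MCS is anchored to health-related quality of
life: item cut-offs are chosen so that each awarded point corresponds to a
15-20 point decrease in IBDQ-32 total (about one clinically significant
difference).  This module fits the univariate anchor regressions, searches
item cut-offs satisfying the 15-20-point rule, performs the diarrhea-item
selection (loose vs Bristol-6 vs Bristol-7 counts), and assembles the final
score table.

Cut-off search: regression-prediction anchoring.  The univariate OLS slope
(IBDQ points per item unit) fixes a uniform category width so that one
awarded point corresponds to a predicted drop in the middle of the target
window; the threshold offset is then chosen to maximize the
between-category variance of IBDQ, which aligns boundaries with natural
gaps in the item's values.  Raw category means are deliberately not used as
the anchor: at cohort scale their sampling error exceeds the width of the
15-20 window, so a mean-matching search latches onto noise.  Categories
with fewer than ``min_category_n`` observations are not allowed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mcs import (
    EXCLUDED_ITEMS,
    INCLUDED_ITEMS,
    MCS_MAX,
    ScoreTable,
    ScoreTableEntry,
    ScoreTableError,
)

__all__ = [
    "AnchorRegressionFit",
    "CalibrationConfig",
    "DegeneratePredictorError",
    "fit_anchor_regression",
    "derive_item_cutoffs",
    "select_diarrhea_item",
    "assemble_score_table",
    "calibrate_score_table",
]


class DegeneratePredictorError(ValueError):
    """Raised when an anchor regression predictor has zero variance."""


@dataclass(frozen=True)
class AnchorRegressionFit:
    """OLS fit of IBDQ-32 total on one item: slope in IBDQ points per item
    unit, with 95% CI and adjusted R^2."""

    slope: float
    intercept: float
    adjusted_r2: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class CalibrationConfig:
    """Anchoring parameters: each awarded point must correspond to a
    predicted IBDQ drop inside [target_drop_min, target_drop_max]; at most
    ``max_points_per_item`` points per item; at least ``min_category_n``
    observations per category.  ``epsilon_r2`` operationalizes a "meaningful"
    adjusted-R^2 gain in the diarrhea-item model comparison."""

    target_drop_min: float = 15.0
    target_drop_max: float = 20.0
    max_points_per_item: int = 3
    min_category_n: int = 5
    epsilon_r2: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.target_drop_min <= self.target_drop_max:
            raise ValueError("need 0 < target_drop_min <= target_drop_max")


def fit_anchor_regression(item_values, ibdq_totals) -> AnchorRegressionFit:
    """Univariate OLS of IBDQ-32 total on an item measurement."""
    x = np.asarray(item_values, dtype=float)
    y = np.asarray(ibdq_totals, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 paired observations")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("item has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return AnchorRegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adjusted_r2=float(model.rsquared_adj),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        n=len(x),
    )


def derive_item_cutoffs(
    item_values,
    ibdq_totals,
    config: CalibrationConfig | None = None,
    item: str | None = None,
) -> ScoreTableEntry | None:
    """Derive cut-offs so each point corresponds to a 15-20 IBDQ-point drop.

    Anchoring uses the regression prediction rather than raw category means
    (whose sampling error at cohort scale exceeds the width of the 15-20
    window): the univariate OLS slope ``b`` (IBDQ points per item unit) sets
    the category width ``w = 17.5/|b|``, so one awarded point corresponds to
    a predicted drop of 17.5 IBDQ points -- the middle of the target window,
    and inside it for any width in ``[15/|b|, 20/|b|]``.  Equally spaced
    thresholds ``t0 + j*w`` are then anchored to the data by choosing the
    offset ``t0`` that maximizes the between-category variance of IBDQ
    (which aligns boundaries with natural gaps in the item's values), under
    the constraint that every category holds at least ``min_category_n``
    observations; the threshold count is capped at ``max_points_per_item``
    and reduced until the occupancy constraint is satisfiable.

    A flat item (non-negative or non-significant slope) carries no points:
    returns ``None`` with a warning.
    """
    config = config or CalibrationConfig()
    x = np.asarray(item_values, dtype=float)
    y = np.asarray(ibdq_totals, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 paired observations")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("item has zero variance")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    if slope >= 0 or float(model.pvalues[1]) > 0.05:
        warnings.warn(
            f"item {item or '?'}: no negative IBDQ association "
            f"(slope {slope:.2f}, p {float(model.pvalues[1]):.3g}); item carries 0 points"
        )
        return None
    target_mid = (config.target_drop_min + config.target_drop_max) / 2.0
    width = target_mid / abs(slope)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    span = xs[-1] - xs[0]
    csum = np.concatenate([[0.0], np.cumsum(ys)])
    # try the full point budget first; category occupancy prunes threshold
    # counts the data range cannot support
    for k in range(config.max_points_per_item, 0, -1):
        # anchor offset: fine grid over one category width above the data
        # floor; ties in the objective (plateaus where no observation changes
        # category) resolve to the plateau middle, centering thresholds in
        # the empty gaps between value clusters
        offsets = xs[0] + np.linspace(0.0, width, 81)[1:]
        ss = np.full(len(offsets), -np.inf)
        for i, t0 in enumerate(offsets):
            thr = t0 + width * np.arange(k)
            bounds = np.searchsorted(xs, thr, side="left")
            edges = np.concatenate([[0], bounds, [n]])
            counts = np.diff(edges)
            if (counts < config.min_category_n).any():
                continue
            means = (csum[edges[1:]] - csum[edges[:-1]]) / counts
            ss[i] = float((counts * means**2).sum())
        if np.isfinite(ss).any():
            near = np.flatnonzero(ss >= ss.max() - 1e-9)
            # middle of the first contiguous run of optimal offsets
            run_end = near[0]
            while run_end + 1 in near:
                run_end += 1
            t0 = float(offsets[(near[0] + run_end) // 2])
            thr = tuple(float(t) for t in t0 + width * np.arange(k))
            return ScoreTableEntry(
                item=item or INCLUDED_ITEMS[0],
                thresholds=thr,
                points=tuple(range(k + 1)),
            )
    warnings.warn(
        f"item {item or '?'}: occupancy constraint leaves no feasible cut-offs; "
        "item carries 0 points"
    )
    return None


@dataclass
class DiarrheaSelection:
    chosen: str
    comparison: pd.DataFrame  # model, adjusted_r2
    multivariate_gain: float
    meaningful_gain: bool
    flat: bool


def select_diarrhea_item(
    cohort: pd.DataFrame,
    ibdq_column: str = "ibdq_total",
    config: CalibrationConfig | None = None,
) -> DiarrheaSelection:
    """Choose the diarrhea item for the score among loose / Bristol-6 /
    Bristol-7 stool counts.

    Fits all univariate models and the two-variable combinations (the full
    triple is exactly collinear, since loose = Bristol 6 + Bristol 7, and is
    excluded); picks the best univariate item by adjusted R^2 and reports
    whether any multivariate model improves adjusted R^2 by more than
    ``epsilon_r2``.
    """
    config = config or CalibrationConfig()
    candidates = ["mean_loose", "mean_b6", "mean_b7"]
    df = cohort[candidates + [ibdq_column]].dropna()
    y = df[ibdq_column].to_numpy(float)
    rows = []

    def fit_model(cols: list[str]):
        xmat = sm.add_constant(df[cols].to_numpy(float))
        return sm.OLS(y, xmat).fit()

    uni, uni_p = {}, {}
    for c in candidates:
        if np.ptp(df[c].to_numpy(float)) == 0:
            rows.append({"model": c, "adjusted_r2": np.nan})
            uni[c], uni_p[c] = -np.inf, 1.0
            continue
        m = fit_model([c])
        uni[c], uni_p[c] = float(m.rsquared_adj), float(m.f_pvalue)
        rows.append({"model": c, "adjusted_r2": uni[c]})
    multi_best = -np.inf
    for pair in itertools.combinations(candidates, 2):
        r2 = float(fit_model(list(pair)).rsquared_adj)
        rows.append({"model": "+".join(pair), "adjusted_r2": r2})
        multi_best = max(multi_best, r2)

    chosen = max(uni, key=uni.get)
    flat = not np.isfinite(uni[chosen]) or uni_p[chosen] > 0.05
    gain = multi_best - uni[chosen]
    if flat:
        warnings.warn("all diarrhea candidates are flat against IBDQ; selection unreliable")
    return DiarrheaSelection(
        chosen=chosen,
        comparison=pd.DataFrame(rows),
        multivariate_gain=float(gain),
        meaningful_gain=bool(gain > config.epsilon_r2),
        flat=flat,
    )


def assemble_score_table(
    entries,
    config: CalibrationConfig | None = None,
) -> ScoreTable:
    """Assemble and validate the final table from per-item entries.

    Entries for the excluded items (mean solid / mean total stools) are
    dropped with a warning.  If the item maxima do not sum to 15 the per-item
    point ceilings are rescaled (largest-remainder on max * 15/total, each
    capped at the config ceiling), with a warning describing the adjustment;
    an impossible total raises a configuration error.
    """
    config = config or CalibrationConfig()
    kept: dict[str, ScoreTableEntry] = {}
    for e in entries:
        if e is None:
            continue
        if e.item in EXCLUDED_ITEMS:
            warnings.warn(f"entry for excluded item {e.item!r} dropped")
            continue
        kept[e.item] = e
    missing = [i for i in INCLUDED_ITEMS if i not in kept]
    if missing:
        raise ScoreTableError(f"missing score-table entries for items: {missing}")
    total = sum(e.max_points for e in kept.values())
    if total != MCS_MAX:
        if len(kept) * config.max_points_per_item < MCS_MAX:
            raise ScoreTableError(
                f"cannot reach total {MCS_MAX} with <= {config.max_points_per_item} "
                "points per item"
            )
        warnings.warn(
            f"item maxima sum to {total}, not {MCS_MAX}; rescaling point ceilings"
        )
        kept = _rescale_entries(kept, config)
    return ScoreTable(entries=tuple(kept[i] for i in INCLUDED_ITEMS))


def _rescale_entries(
    kept: dict[str, ScoreTableEntry], config: CalibrationConfig
) -> dict[str, ScoreTableEntry]:
    """Adjust per-item point ceilings to sum to 15 by merging or extending
    threshold grids proportionally (largest-remainder apportionment)."""
    items = list(INCLUDED_ITEMS)
    current = np.array([kept[i].max_points for i in items], dtype=float)
    weights = np.where(current > 0, current, 0.5)
    raw = weights * MCS_MAX / weights.sum()
    target = np.minimum(np.floor(raw), config.max_points_per_item).astype(int)
    target = np.maximum(target, 1)
    while target.sum() < MCS_MAX:
        frac = raw - target
        frac[target >= config.max_points_per_item] = -np.inf
        target[int(np.argmax(frac))] += 1
    while target.sum() > MCS_MAX:
        frac = raw - target
        frac[target <= 1] = np.inf
        target[int(np.argmin(frac))] -= 1
    out = {}
    for item, t in zip(items, target):
        e = kept[item]
        t = int(t)
        if e.max_points == t:
            out[item] = e
        elif e.max_points > t:  # merge top categories
            out[item] = ScoreTableEntry(
                item=item, thresholds=e.thresholds[:t], points=tuple(range(t + 1))
            )
        else:  # extend grid by splitting the widest interior gap
            thr = list(e.thresholds)
            while len(thr) < t:
                grid = [0.0, *thr]
                gaps = np.diff(grid)
                j = int(np.argmax(gaps))
                thr.insert(j, grid[j] + gaps[j] / 2.0)
                thr = sorted(thr)
            out[item] = ScoreTableEntry(
                item=item, thresholds=tuple(thr), points=tuple(range(t + 1))
            )
    return out


def calibrate_score_table(
    cohort: pd.DataFrame,
    config: CalibrationConfig | None = None,
    ibdq_column: str = "ibdq_total",
) -> tuple[ScoreTable, DiarrheaSelection]:
    """Full calibration: select the diarrhea item, derive cut-offs for each
    of the five included items against IBDQ-32 total, and assemble the table.

    The diarrhea selection decides which loose-stool variant anchors the
    ``mean_loose`` slot (the score always records the loose-stool item;
    selection is reported for audit).
    """
    config = config or CalibrationConfig()
    selection = select_diarrhea_item(cohort, ibdq_column=ibdq_column, config=config)
    entries = []
    for item in INCLUDED_ITEMS:
        df = cohort[[item, ibdq_column]].dropna()
        entry = derive_item_cutoffs(
            df[item].to_numpy(float), df[ibdq_column].to_numpy(float),
            config=config, item=item,
        )
        if entry is None:
            # flat item: keep a degenerate single-threshold entry at the
            # median so assembly can rescale; flagged by derive_item_cutoffs
            entry = ScoreTableEntry(
                item=item,
                thresholds=(float(np.median(df[item])) or 0.5,),
                points=(0, 1),
            )
        entries.append(entry)
    table = assemble_score_table(entries, config=config)
    return table, selection
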