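"""ROC analysis of the MCS against reference labels: disease activity by the
Hjortswang criteria and cluster-derived severity groups.

AUC is computed tie-aware (trapezoid over the ROC curve, which equals the
Mann-Whitney concordance probability).  Cut-offs are chosen by Youden's J
(sensitivity + specificity - 1), with a closest-to-(0,1) criterion available,
and reported on the integer score scale as "MCS >= c".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "UndefinedAUCError",
    "roc_curve",
    "mann_whitney_auc",
    "optimal_cutoff",
    "evaluate_severity_contrasts",
]


class UndefinedAUCError(ValueError):
    """Raised when a ROC curve is requested with only one class present."""


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    chosen_cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    criterion: str | None = None
    flat: bool = False


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the concordance probability P(score_pos > score_neg) with ties
    counted half -- computed by direct pair counting via rank sums."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("both classes must be present")
    # midranks handle ties exactly
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_curve(scores, labels) -> ROCResult:
    """Tie-aware ROC curve over the unique score values, with trapezoid AUC.

    ``labels`` are binary (1 = positive class); higher scores are assumed to
    indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedAUCError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_cutoff(roc: ROCResult, criterion: str = "youden") -> ROCResult:
    """Choose the operating point on a ROC curve.

    ``youden`` maximizes J = sensitivity + specificity - 1; ties are broken
    toward the lower cut-off (favoring sensitivity).  ``closest01`` minimizes
    the Euclidean distance to the perfect corner (0, 1).  A flat curve
    (J = 0 everywhere) is flagged.
    """
    sens = roc.tpr
    spec = 1.0 - roc.fpr
    if criterion == "youden":
        j = sens + spec - 1.0
        best = float(j.max())
        # ties -> lower cutoff = later index in the descending-threshold sweep
        idx = int(np.flatnonzero(np.isclose(j, best)).max())
        flat = bool(np.isclose(best, 0.0))
    elif criterion == "closest01":
        d = np.hypot(roc.fpr, 1.0 - roc.tpr)
        idx = int(np.flatnonzero(np.isclose(d, d.min())).max())
        flat = bool(np.isclose((sens + spec - 1.0).max(), 0.0))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ROCResult(
        thresholds=roc.thresholds,
        fpr=roc.fpr,
        tpr=roc.tpr,
        auc=roc.auc,
        chosen_cutoff=float(roc.thresholds[idx]),
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        criterion=criterion,
        flat=flat,
    )


_SEVERITY_ORDER = ("remission", "partial remission", "mild", "moderate", "severe")


def evaluate_severity_contrasts(
    mcs_values,
    hjortswang_active,
    cluster_annotations,
    criterion: str = "youden",
) -> dict[str, ROCResult]:
    """One ROC per severity contrast of the MCS.

    Contrasts: active vs remission by the Hjortswang criteria; any active
    disease (mild or worse), moderate-or-severe, and severe disease by the
    cluster annotation.  Contrasts with a single class are skipped with a
    warning.  The chosen cut-off is reported as the smallest integer c for
    which "MCS >= c" attains the optimal operating point.
    """
    mcs_values = np.asarray(mcs_values, dtype=float)
    ann = np.asarray(cluster_annotations, dtype=object)
    rank = {name: i for i, name in enumerate(_SEVERITY_ORDER)}
    # cluster annotations may carry disambiguating suffixes ("remission (i)")
    levels = np.array([rank[str(a).split(" (")[0]] for a in ann])
    contrasts = {
        "hjortswang_active": np.asarray(hjortswang_active).astype(int),
        "any_active": (levels >= rank["mild"]).astype(int),
        "moderate_or_severe": (levels >= rank["moderate"]).astype(int),
        "severe": (levels >= rank["severe"]).astype(int),
    }
    out: dict[str, ROCResult] = {}
    for name, labels in contrasts.items():
        if labels.min() == labels.max():
            warnings.warn(f"contrast {name!r} has a single class; skipped")
            continue
        res = optimal_cutoff(roc_curve(mcs_values, labels), criterion=criterion)
        # report integer convention "MCS >= c": smallest integer cutoff giving
        # the same classification as the chosen real-valued threshold
        res.chosen_cutoff = float(np.ceil(res.chosen_cutoff)) if np.isfinite(res.chosen_cutoff) else res.chosen_cutoff
        out[name] = res
    return out
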