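"""ROC analysis of an ordinal score from grouped counts.

For a score with a handful of ordered levels the ROC curve is fully
determined by the per-level positive/negative counts: one operating point
per threshold between adjacent levels ("positive" means score strictly
above the threshold), plus the (0,0) and (1,1) anchors. The trapezoidal
area under this polygon equals the tie-corrected rank probability
P(score_pos > score_neg) + 0.5 * P(tie). The optimal cut-off maximizes the
Youden index J = sensitivity + specificity - 1 and is reported as the
midpoint of the two adjacent score levels bracketing the chosen threshold
(which need not be an attainable score value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class GroupedROC:
    score_levels: np.ndarray  # increasing
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    points: np.ndarray  # (k+1) x 2 array of (1-specificity, sensitivity)
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float

    @property
    def n_pos(self) -> int:
        return int(self.pos_counts.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg_counts.sum())


def roc_points(
    score_levels: Sequence[float],
    pos_counts: Sequence[int],
    neg_counts: Sequence[int],
) -> np.ndarray:
    """Operating points (1-specificity, sensitivity) from grouped counts.

    Ordered from (0, 0) (threshold above the top level: nothing called
    positive) down to (1, 1) (everything positive).
    """
    levels = np.asarray(score_levels, dtype=float)
    pos = np.asarray(pos_counts, dtype=np.int64)
    neg = np.asarray(neg_counts, dtype=np.int64)
    if levels.ndim != 1 or levels.size < 2:
        raise ValueError("need at least two score levels")
    if not (np.diff(levels) > 0).all():
        raise ValueError("score levels must be strictly increasing")
    if pos.shape != levels.shape or neg.shape != levels.shape:
        raise ValueError("counts must align with score levels")
    if (pos < 0).any() or (neg < 0).any():
        raise ValueError("counts must be non-negative")
    n_pos, n_neg = pos.sum(), neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    # cumulative counts strictly above each threshold index k (levels[k:])
    tail_pos = np.concatenate([np.cumsum(pos[::-1])[::-1], [0]])
    tail_neg = np.concatenate([np.cumsum(neg[::-1])[::-1], [0]])
    fpr = tail_neg[::-1] / n_neg
    tpr = tail_pos[::-1] / n_pos
    return np.column_stack([fpr, tpr])


def trapezoid_auc(points: np.ndarray) -> float:
    """Trapezoidal area under operating points sorted by 1-specificity."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least two operating points")
    fpr, tpr = points[:, 0], points[:, 1]
    if (np.diff(fpr) < 0).any():
        raise ValueError("points must be sorted by 1-specificity")
    return float(np.trapezoid(tpr, fpr))


def auc_ci_hanley_mcneil(
    auc: float, n_pos: int, n_neg: int
) -> tuple[float, float, float]:
    """Hanley-McNeil standard error and 95% CI for a trapezoidal AUC.

    Returns ``(lower, upper, se)``; the interval auc +/- 1.96*se is clipped
    to [0, 1].
    """
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie strictly in (0, 1)")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(var))
    return (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se), se)


def youden_cutoff(roc: "GroupedROC") -> tuple[float, float, float]:
    """Youden-optimal cut-off: ``(cutoff, sensitivity, specificity)``.

    J = sensitivity + specificity - 1 is maximized over interior operating
    points; ties break toward higher specificity. The cut-off is the
    midpoint of the adjacent score levels bracketing the chosen threshold.
    """
    return _youden(roc.score_levels, roc.points)


def _youden(levels: np.ndarray, points: np.ndarray) -> tuple[float, float, float]:
    # interior points: index i in points corresponds to "positive iff
    # score > levels[len-1-i]" for i = 1..k-1 after the (0,0) anchor;
    # reconstruct the bracketing pair from the point index directly.
    k = levels.size
    if points.shape[0] != k + 1:
        raise ValueError("points do not match the score levels")
    if k < 2:
        raise ValueError("need at least one interior operating point")
    best = None
    for i in range(1, k):  # interior operating points only
        fpr, tpr = points[i]
        j = tpr - fpr
        spec = 1.0 - fpr
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[3]
        ):
            best = (j, i, tpr, spec)
    _, i, sens, spec = best
    # point i sits between levels[k-i-1] and levels[k-i]
    cutoff = 0.5 * (levels[k - i - 1] + levels[k - i])
    return float(cutoff), float(sens), float(spec)


def grouped_roc(
    score_levels: Sequence[float],
    pos_counts: Sequence[int],
    neg_counts: Sequence[int],
) -> GroupedROC:
    """Full grouped ROC: points, trapezoidal AUC with Hanley-McNeil CI,
    and the Youden-optimal cut-off."""
    levels = np.asarray(score_levels, dtype=float)
    pos = np.asarray(pos_counts, dtype=np.int64)
    neg = np.asarray(neg_counts, dtype=np.int64)
    points = roc_points(levels, pos, neg)
    auc = trapezoid_auc(points)
    if 0.0 < auc < 1.0:
        lo, hi, se = auc_ci_hanley_mcneil(auc, int(pos.sum()), int(neg.sum()))
    else:  # degenerate discrimination: the Hanley-McNeil variance is zero
        lo = hi = auc
        se = 0.0
    cutoff, sens, spec = _youden(levels, points)
    return GroupedROC(
        score_levels=levels,
        pos_counts=pos,
        neg_counts=neg,
        points=points,
        auc=auc,
        auc_se=se,
        auc_ci=(lo, hi),
        cutoff=cutoff,
        cutoff_sensitivity=sens,
        cutoff_specificity=spec,
    )
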