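"""Evaluation metrics and affinity transforms.

All threshold metrics are exact evaluations of the standard confusion-count
formulas (accuracy, sensitivity, specificity, precision, recall, F1, MCC).
Spearman's rank correlation uses the tie-free shortcut
``1 - 6*sum(d_i^2) / (n*(n^2-1))`` when ranks are unique and rank-averaged
Pearson correlation otherwise; AUC is the Mann-Whitney rank statistic with
tie correction.  Undefined metrics (zero denominators, single-class label
vectors, n < 2) are reported as NaN, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.stats import rankdata

IC50_MAX = 50000.0
BINDER_THRESHOLD_NM = 500.0


def ic50_to_target(ic50) -> np.ndarray | float:
    """Map an IC50 affinity in nM onto [0, 1]: ``1 - log(ic50)/log(50000)``.

    The standard transform for IEDB-style regression targets; values are
    clipped to [0, 1] so affinities above 50000 nM score 0.
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ic50 must be positive")
    out = np.clip(1.0 - np.log(arr) / np.log(IC50_MAX), 0.0, 1.0)
    return float(out) if np.isscalar(ic50) else out


def binarize(ic50, threshold: float = BINDER_THRESHOLD_NM) -> np.ndarray | int:
    """Binder label: 1 iff IC50 is strictly below ``threshold`` (500 nM)."""
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ic50 must be positive")
    out = (arr < threshold).astype(int)
    return int(out) if np.isscalar(ic50) else out


#: Regression-target score equivalent of the 500 nM binder cut-off.
TARGET_BINDER_SCORE = 1.0 - math.log(BINDER_THRESHOLD_NM) / math.log(IC50_MAX)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies at a fixed score threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "ConfusionCounts":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
        pred = s >= threshold
        return cls(
            tp=int(np.sum(pred & (y == 1))),
            tn=int(np.sum(~pred & (y == 0))),
            fp=int(np.sum(pred & (y == 0))),
            fn=int(np.sum(~pred & (y == 1))),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); also called recall."""
    return _ratio(c.tp, c.tp + c.fn)


recall = sensitivity


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN/(TN+FP)."""
    return _ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        return float("nan")
    return 2 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NaN when any marginal sum is zero."""
    denom = (
        (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return float("nan")
    return ((c.tp * c.tn) - (c.fn * c.fp)) / math.sqrt(denom)


def srcc(x, y) -> float:
    """Spearman's rank correlation coefficient.

    Tie-free inputs use the shortcut ``1 - 6*sum(d_i^2)/(n*(n^2-1))``;
    inputs with ties use Pearson correlation of average ranks (both paths
    agree on tie-free data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("srcc expects two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free:
        d = rx - ry
        return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Tie-corrected (average ranks), hence equal to the trapezoidal area
    under :func:`roc_curve`.  NaN when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return (float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve(scores, labels) -> List[Tuple[float, float]]:
    """(FPR, TPR) points from (0,0) to (1,1), one per distinct threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve requires both classes")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(s)):
        if y[i] == 1:
            tp += 1
        else:
            fp += 1
        # emit a point only at the end of a run of tied scores
        if i == len(s) - 1 or s[i + 1] != s[i]:
            points.append((fp / n_neg, tp / n_pos))
    return points
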