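"""Confusion-matrix metrics, ROC curves and AUC for good/poor sleep prediction.

The positive class is good-quality sleep throughout: sensitivity (recall) is
the fraction of good-sleep instances detected, specificity the fraction of
poor-sleep instances correctly rejected. Metrics are evaluated as exact
rationals from integer confusion-matrix cells and reported at 4 decimal
places (round-half-even). AUC is the area under the ROC curve by the
trapezoidal rule over all distinct thresholds, which coincides with the
rank-statistic definition: the probability that a randomly chosen positive
instance is scored higher than a randomly chosen negative one (ties count
one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "evaluate_predictions",
    "implied_confusion",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer prediction-vs-truth counts (positive class = good sleep)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion matrix must count at least one instance")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """All scalar metrics (None where the denominator is zero) plus ROC."""

    accuracy: float | None
    precision: float | None
    recall_sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    def rounded(self, ndigits: int = 4) -> dict:
        """Metrics rounded half-even to table precision."""
        out = {}
        for name in ("accuracy", "precision", "recall_sensitivity", "specificity", "f1", "auc"):
            value = getattr(self, name)
            out[name] = None if value is None else round(value, ndigits)
        return out


def confusion(labels, predictions) -> ConfusionMatrix:
    """Tabulate binary labels vs predictions (1/"good" = positive)."""
    y = _binarize(labels)
    p = _binarize(predictions)
    if len(y) != len(p):
        raise ValueError("labels and predictions must have equal length")
    if len(y) == 0:
        raise ValueError("need at least one instance")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _binarize(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        return (arr == "good").astype(int)
    return (arr.astype(float) >= 0.5).astype(int) if arr.dtype.kind == "f" else arr.astype(int)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else float(Fraction(num, den))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Exact rational accuracy, precision, recall, specificity and F1.

    A metric whose denominator is zero (degenerate one-class input) is
    returned as None, not as 0.
    """
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        # harmonic mean of precision and recall = 2tp / (2tp + fp + fn)
        f1 = float(Fraction(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn))
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall_sensitivity=recall,
        specificity=specificity,
        f1=f1,
    )


def roc_auc(labels, confidences) -> tuple[list[tuple[float, float]], float]:
    """ROC points by sweeping all distinct thresholds, AUC by trapezoid.

    Returns ``(roc_points, auc)`` with points as (FPR, TPR) from (0, 0) to
    (1, 1), monotone nondecreasing in both coordinates. Equals the pairwise
    rank statistic (ties counted 1/2) up to floating-point rounding.
    """
    y = _binarize(labels)
    s = np.asarray(confidences, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and confidences must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        # consume all instances sharing one score (one threshold step)
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, auc


def evaluate_predictions(labels, confidences, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold the confidences at 0.5, add ROC and AUC."""
    s = np.asarray(confidences, dtype=float)
    cm = confusion(labels, (s >= threshold).astype(int))
    base = metrics_from_confusion(cm)
    points, auc = roc_auc(labels, s)
    return MetricsReport(
        accuracy=base.accuracy,
        precision=base.precision,
        recall_sensitivity=base.recall_sensitivity,
        specificity=base.specificity,
        f1=base.f1,
        auc=auc,
        roc_points=points,
    )


def implied_confusion(
    sensitivity: float | str,
    specificity: float | str,
    n_pos: int,
    n_neg: int,
) -> ConfusionMatrix:
    """Reconstruct the integer confusion matrix behind printed sensitivity/specificity.

    Published reports often print only rounded metrics; over a known test
    composition (``n_pos`` positives, ``n_neg`` negatives) the integer cell
    counts are recoverable when exactly one (tp, tn) pair rounds to the
    printed values at their printed precision. Pass the printed value as a
    string (e.g. ``"0.333"``, ``"1.000"``) to preserve its precision; a float
    is taken at 4 decimal places. Raises if no pair or more than one pair
    matches.
    """
    def matches(value: int, total: int, printed: float | str) -> bool:
        if isinstance(printed, str):
            decimals = len(printed.split(".")[1]) if "." in printed else 0
            target = float(printed)
        else:
            decimals, target = 4, printed
        return round(value / total, decimals) == round(target, decimals)

    tps = [tp for tp in range(n_pos + 1) if matches(tp, n_pos, sensitivity)]
    tns = [tn for tn in range(n_neg + 1) if matches(tn, n_neg, specificity)]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"printed sensitivity/specificity do not imply a unique matrix "
            f"(candidates: {tps} / {tns})"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
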