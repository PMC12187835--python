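"""Confusion-count metrics and ROC analysis for patch and whole-slide testing.

Metrics follow the clinical-validation convention for binary tumor/non-tumor
classification: accuracy (ACC), sensitivity (SEN, recall on the tumor class),
specificity (SPE), precision, F1 (harmonic mean of precision and recall) and
the support-weighted F1 across both classes. A metric whose denominator is
zero (e.g. sensitivity on a slide with no positive ground-truth cells) is
reported as 0.0 and flagged as degenerate rather than returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "compute_metrics",
    "weighted_f1",
    "roc_auc",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs (e.g. ROC with one class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Cell-wise TP/TN/FP/FN tallies of a binary comparison."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Validation measures derived from a :class:`ConfusionCounts`.

    ``degenerate`` lists metrics whose denominator was zero; those values are
    reported as 0.0 by convention.
    """

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    weighted_f1: float
    auc: float | None = None
    degenerate: frozenset[str] = field(default_factory=frozenset)


def _ratio(num: int, den: int, name: str, degenerate: set[str]) -> float:
    if den == 0:
        degenerate.add(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """ACC=(TP+TN)/total, SEN=TP/(TP+FN), SPE=TN/(TN+FP), precision=TP/(TP+FP),
    F1 = 2TP/(2TP+FP+FN), plus the support-weighted F1.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on all-zero confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    degen: set[str] = set()
    acc = (tp + tn) / counts.total
    sen = _ratio(tp, tp + fn, "sensitivity", degen)
    spe = _ratio(tn, tn + fp, "specificity", degen)
    pre = _ratio(tp, tp + fp, "precision", degen)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", degen)
    wf1 = weighted_f1(counts)
    return MetricsReport(
        counts=counts,
        accuracy=acc,
        sensitivity=sen,
        specificity=spe,
        precision=pre,
        f1=f1,
        weighted_f1=wf1,
        auc=auc,
        degenerate=frozenset(degen),
    )


def weighted_f1(counts: ConfusionCounts) -> float:
    """Support-weighted mean of the per-class F1 scores.

    The negative-class F1 treats negatives as the class of interest, i.e. its
    true positives are the TN cells: F1_neg = 2TN/(2TN+FN+FP). Weights are the
    ground-truth supports (TP+FN) and (TN+FP).
    """
    if counts.total == 0:
        raise ValueError("cannot compute weighted F1 on all-zero confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    f1_pos = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    f1_neg = 2 * tn / (2 * tn + fn + fp) if (2 * tn + fn + fp) > 0 else 0.0
    return ((tp + fn) * f1_pos + (tn + fp) * f1_neg) / counts.total


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Area under the ROC curve with tie-aware trapezoidal integration.

    Parameters
    ----------
    scores
        Predicted positive-class probabilities (or any monotone scores).
    labels
        Binary ground truth; truthy/1 marks the positive class.

    Returns
    -------
    (auc, fpr, tpr, thresholds)

    Raises
    ------
    UndefinedMetricError
        If only one class is present in ``labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shapes")
    if labels.all() or not labels.any():
        raise UndefinedMetricError("ROC AUC is undefined with a single class present")
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
    return float(_sk_auc(fpr, tpr)), fpr, tpr, thr
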