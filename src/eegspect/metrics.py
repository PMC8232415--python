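"""Binary-classification metric suite.

Sensitivity, specificity and accuracy are percentages computed from the
confusion counts; F1 is on the 0-1 scale; AUC is the trapezoidal area
under the empirical ROC curve (equal to the normalized Mann-Whitney U
statistic, with tied scores handled by the midrank convention). ASD is the
positive class throughout.

A metric whose denominator is zero (e.g. specificity with no true
negatives or false positives in the sample) is reported as None, never
silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @staticmethod
    def from_labels(y_true, y_pred) -> "ConfusionCounts":
        """Counts from 0/1 label arrays (1 = ASD, the positive class)."""
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label arrays must have equal length")
        return ConfusionCounts(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    """Headline metrics plus an optional per-fold breakdown.

    sensitivity/specificity/accuracy are percentages (0-100); f1 and auc
    are on the 0-1 scale; any undefined entry is None.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    auc: float | None = None
    confusion: ConfusionCounts | None = None
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }
        if self.confusion is not None:
            out["confusion"] = {
                "tp": self.confusion.tp, "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn,
            }
        if self.per_fold:
            out["per_fold"] = [m.to_dict() if isinstance(m, MetricsReport) else m for m in self.per_fold]
        return out


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity/specificity/accuracy (%) and F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion table")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    f1_den = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / f1_den if f1_den > 0 else None
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, confusion=c)


def compute_roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """Empirical ROC curve and its trapezoidal area.

    scores: continuous classifier scores, larger = more ASD-like;
    labels: 0/1 with 1 = ASD. Returns (auc, fpr, tpr) with one ROC point
    per distinct score threshold (plus the origin). The trapezoid over
    tied-score groups reproduces the midrank Mann-Whitney convention, so
    constant scores give AUC 0.5 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # collapse tied scores into single thresholds
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], dtype=int)
    cut = np.r_[distinct, s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[cut]
    fps = np.cumsum(1 - y_sorted)[cut]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr
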