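"""Confusion-matrix metrics and ROC/AUC for imbalanced binary calls.

Sensitivity, specificity, accuracy and the Matthews correlation coefficient
are computed from the confusion counts:

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    Mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is the trapezoidal area under the ROC curve over all score thresholds,
which with half-credit for ties equals the Mann-Whitney pair statistic.
A metric whose denominator vanishes (reachable under heavy class imbalance)
is reported as NaN and flagged in ``undefined`` — never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValidationError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    undefined: frozenset = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "sen": self.sen, "spe": self.spe, "acc": self.acc, "mcc": self.mcc,
            "auc": self.auc,
            "undefined": sorted(self.undefined),
        }


def _as_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValidationError(f"{name} must be nonempty")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 values")
    return arr.astype(np.int64)


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN; the four counts partition the samples."""
    y = _as_binary(labels, "labels")
    c = _as_binary(calls, "calls")
    if y.shape != c.shape:
        raise ValidationError(f"length mismatch: {y.size} labels vs {c.size} calls")
    return ConfusionCounts(
        tp=int(((y == 1) & (c == 1)).sum()),
        tn=int(((y == 0) & (c == 0)).sum()),
        fp=int(((y == 0) & (c == 1)).sum()),
        fn=int(((y == 1) & (c == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sen/Spe/Acc/Mcc from confusion counts, flagging undefined metrics."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined = set()

    if tp + fn > 0:
        sen = tp / (tp + fn)
    else:
        sen = math.nan
        undefined.add("sen")
    if tn + fp > 0:
        spe = tn / (tn + fp)
    else:
        spe = math.nan
        undefined.add("spe")
    acc = (tp + tn) / counts.total

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = math.nan
        undefined.add("mcc")

    return MetricsReport(
        counts=counts, sen=sen, spe=spe, acc=acc, mcc=mcc,
        undefined=frozenset(undefined),
    )


def roc_curve(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr) at every distinct score threshold, from (0,0)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValidationError(f"length mismatch: {y.size} labels vs {s.size} scores")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes to be present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # keep the last index of each tie group: one ROC point per threshold
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tpr = np.cumsum(y_sorted)[idx] / n_pos
    fpr = np.cumsum(1 - y_sorted)[idx] / n_neg
    return np.r_[0.0, fpr], np.r_[0.0, tpr]


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal AUC; ties between classes receive half credit."""
    fpr, tpr = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    labels: Sequence[int],
    probs: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report from positive-class probabilities (call = 1 iff p >= t)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be inside (0, 1), got {threshold}")
    p = np.asarray(probs, dtype=np.float64)
    calls = (p >= threshold).astype(np.int64)
    report = compute_metrics(confusion(labels, calls))
    y = np.asarray(labels)
    if 0 < y.sum() < y.size:
        report.auc = roc_auc(labels, probs)
    else:
        report.undefined = report.undefined | {"auc"}
    return report
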