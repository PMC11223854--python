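"""Evaluation mathematics for hexapeptide classification and APR segmentation.

Threshold-free ranking quality is measured by the areas under the ROC curve
(recall vs 1 - specificity, trapezoidal) and the precision-recall curve
(non-interpolated step summation, i.e. average precision). The default
operating threshold is chosen by Youden's J statistic,
``J = recall + specificity - 1``. Segment-level agreement between predicted
and annotated aggregation-prone regions uses the refined Segment OVerlap
score (SOV), computed separately for APR and non-APR segments on a 0-100
scale.

Ratio metrics with a zero denominator are returned as NaN (a flagged
undefined value) and are excluded from macro averages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn import metrics as _skm

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "Curve",
    "SOVResult",
    "confusion",
    "precision_recall_specificity",
    "roc_curve",
    "pr_curve",
    "youden_threshold",
    "segments",
    "sov",
    "sov_both",
    "macro_average",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / FN / TN tallies of a binary prediction."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class Curve:
    """An ROC or PR curve with its thresholds and area."""

    kind: str  # "ROC" | "PR"
    x: np.ndarray  # ROC: 1 - specificity; PR: recall
    y: np.ndarray  # ROC: recall;          PR: precision
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class SOVResult:
    """Segment overlap scores for the APR and non-APR classes, in [0, 100]."""

    sov_apr: float
    sov_non_apr: float


def _as_binary(v: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(np.int64)


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/FN/TN; positives are amyloid/APR (label 1)."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: pred {p.size} vs truth {t.size}")
    return ConfusionCounts(
        TP=int(np.sum((p == 1) & (t == 1))),
        FP=int(np.sum((p == 1) & (t == 0))),
        FN=int(np.sum((p == 0) & (t == 1))),
        TN=int(np.sum((p == 0) & (t == 0))),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning NaN", what)
        return math.nan
    return num / den


def precision_recall_specificity(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, specificity); NaN flags an undefined ratio."""
    prec = _ratio(c.TP, c.TP + c.FP, "precision")
    rec = _ratio(c.TP, c.TP + c.FN, "recall")
    spec = _ratio(c.TN, c.FP + c.TN, "specificity")
    return prec, rec, spec


def roc_curve(scores: Sequence[float], truth: Sequence[int]) -> Curve:
    """ROC curve (one point per distinct score, ties share a threshold) and
    its trapezoidal area."""
    t = _as_binary(truth, "truth")
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    if t.min() == t.max():
        raise ValueError("ROC curve requires both classes in truth")
    fpr, tpr, thr = _skm.roc_curve(t, s, drop_intermediate=False)
    return Curve(kind="ROC", x=fpr, y=tpr, thresholds=thr,
                 auc=float(np.trapezoid(tpr, fpr)))


def pr_curve(scores: Sequence[float], truth: Sequence[int]) -> Curve:
    """Precision-recall curve with non-interpolated (step) area, i.e. the
    average-precision summation."""
    t = _as_binary(truth, "truth")
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    if t.sum() == 0:
        raise ValueError("PR curve requires at least one positive in truth")
    prec, rec, thr = _skm.precision_recall_curve(t, s)
    return Curve(kind="PR", x=rec, y=prec, thresholds=thr,
                 auc=float(_skm.average_precision_score(t, s)))


def youden_threshold(roc: Curve) -> tuple[float, float]:
    """Threshold maximizing J = recall + specificity - 1 on an ROC curve.

    Ties are broken toward the smallest finite threshold. Scores >= threshold
    classify as positive.
    """
    if roc.kind != "ROC":
        raise ValueError("youden_threshold expects an ROC curve")
    j = roc.y - roc.x  # tpr - fpr
    best_j = float(j.max())
    candidates = np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))
    finite = [i for i in candidates if np.isfinite(roc.thresholds[i])]
    idx = min(finite, key=lambda i: roc.thresholds[i]) if finite else candidates[0]
    thr = float(roc.thresholds[idx])
    return thr, best_j


def segments(labels: Sequence[int], target: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of `target` as 0-based half-open [start, end) intervals."""
    arr = _as_binary(labels, "labels")
    segs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(arr):
        if v == target and start is None:
            start = i
        elif v != target and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(arr)))
    return segs


def _sov_for_class(pred_segs: list[tuple[int, int]],
                   true_segs: list[tuple[int, int]]) -> float:
    """Refined SOV over one class's segmentations (0-100 scale).

    For every overlapping (reference, predicted) pair the score credits
    ``(minov + delta) / maxov`` weighted by the reference length, where
    ``minov`` is the intersection, ``maxov`` the span of the union, and the
    allowance ``delta = min(maxov - minov, minov, len_ref//2, len_pred//2)``.
    Reference segments with no overlapping prediction enter the normalizer
    only. Returns NaN when the reference has no segments of this class.
    """
    total = 0.0
    norm = 0
    for (ts, te) in true_segs:
        tlen = te - ts
        overlapped = False
        for (ps, pe) in pred_segs:
            minov = min(te, pe) - max(ts, ps)
            if minov <= 0:
                continue
            overlapped = True
            maxov = max(te, pe) - min(ts, ps)
            plen = pe - ps
            delta = min(maxov - minov, minov, tlen // 2, plen // 2)
            total += tlen * (minov + delta) / maxov
            norm += tlen
        if not overlapped:
            norm += tlen
    if norm == 0:
        return math.nan
    return 100.0 * total / norm


def sov(pred_labels: Sequence[int], true_labels: Sequence[int],
        positive: bool = True) -> float:
    """Segment OVerlap score for the APR (positive=True) or non-APR class."""
    p = _as_binary(pred_labels, "pred_labels")
    t = _as_binary(true_labels, "true_labels")
    if p.shape != t.shape:
        raise ValueError("pred_labels and true_labels must have equal length")
    target = 1 if positive else 0
    return _sov_for_class(segments(p, target), segments(t, target))


def sov_both(pred_labels: Sequence[int], true_labels: Sequence[int]) -> SOVResult:
    return SOVResult(
        sov_apr=sov(pred_labels, true_labels, positive=True),
        sov_non_apr=sov(pred_labels, true_labels, positive=False),
    )


def macro_average(values: Iterable[float]) -> float:
    """Mean over defined (non-NaN) values; NaN if none are defined."""
    arr = np.asarray(list(values), dtype=np.float64)
    defined = arr[~np.isnan(arr)]
    if defined.size < arr.size:
        logger.warning("macro average excludes %d undefined value(s)",
                       arr.size - defined.size)
    return float(defined.mean()) if defined.size else math.nan
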