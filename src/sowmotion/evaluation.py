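"""Event-based detection scoring and frame-level classification metrics.

A detected transition counts as a true positive when its interval coincides
with (overlaps) an annotated transition interval, the annotation first being
dilated by a tolerance on each side to absorb sensor/video synchronisation
error.  Multiple detections coinciding with one annotation are a single
correct result; an annotation with no coinciding detection is a false
negative; a detection coinciding with no annotation is a false positive.
Precision, recall and F1 follow from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .sensor_io import POSTURE_LABELS

__all__ = [
    "EventCounts",
    "EvalMetrics",
    "match_events",
    "precision",
    "recall",
    "f1",
    "metrics_from_counts",
    "frame_confusion",
]


@dataclass(frozen=True)
class EventCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("event counts must be non-negative")

    @property
    def n_annotated(self) -> int:
        """Number of annotated transition events (TP + FN)."""
        return self.tp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    f1: float


def _intervals(objs) -> list[tuple[float, float]]:
    out = []
    for o in objs:
        if hasattr(o, "interval"):
            out.append(o.interval)
        else:
            out.append((float(o[0]), float(o[1])))
    return out


def match_events(detected, annotated, tolerance_s: float = 2.0) -> EventCounts:
    """Match detected segments to annotated transition intervals.

    Parameters
    ----------
    detected : sequence of TransitionSegment or (start, end) pairs, time-sorted.
    annotated : sequence of (start, end) pairs, time-sorted.
    tolerance_s : dilation applied to each annotation on both sides.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    det = _intervals(detected)
    ann = _intervals(annotated)
    for name, ivs in (("detected", det), ("annotated", ann)):
        if any(b[0] < a[0] for a, b in zip(ivs, ivs[1:])):
            raise ValueError(f"{name} intervals must be time-sorted")
    matched_ann = np.zeros(len(ann), dtype=bool)
    fp = 0
    starts = np.array([a[0] - tolerance_s for a in ann])
    ends = np.array([a[1] + tolerance_s for a in ann])
    for ds, de in det:
        hit = (ds <= ends) & (de >= starts) if len(ann) else np.zeros(0, dtype=bool)
        if hit.any():
            matched_ann |= hit
        else:
            fp += 1
    tp = int(matched_ann.sum())
    return EventCounts(tp=tp, fp=fp, fn=len(ann) - tp)


def precision(c: EventCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no detections (TP + FP = 0)")
    return c.tp / (c.tp + c.fp)


def recall(c: EventCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no annotated events (TP + FN = 0)")
    return c.tp / (c.tp + c.fn)


def f1(precision_value: float, recall_value: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision_value + recall_value == 0:
        return 0.0
    return 2.0 * recall_value * precision_value / (recall_value + precision_value)


def metrics_from_counts(c: EventCounts) -> EvalMetrics:
    p, r = precision(c), recall(c)
    return EvalMetrics(precision=p, recall=r, f1=f1(p, r))


def frame_confusion(true_labels, predicted_labels, labels=POSTURE_LABELS):
    """Frame-level confusion matrix (rows=true, cols=predicted) and per-class F1.

    Returns
    -------
    (matrix, per_class_f1, mean_f1) where ``matrix`` is a labelled DataFrame,
    ``per_class_f1`` a Series indexed by class, and ``mean_f1`` the
    unweighted mean across classes.  A class absent from both truth and
    predictions gets F1 = 0 by the one-vs-rest convention (flagged NaN-free
    so the unweighted mean stays defined).
    """
    t = np.asarray(true_labels)
    y = np.asarray(predicted_labels)
    if t.shape != y.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {y.shape} predicted")
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    mat = np.zeros((k, k), dtype=int)
    for a, b in zip(t, y):
        mat[idx[a], idx[b]] += 1
    tp = np.diag(mat).astype(float)
    row = mat.sum(axis=1).astype(float)  # true counts
    col = mat.sum(axis=0).astype(float)  # predicted counts
    denom = row + col
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    matrix = pd.DataFrame(mat, index=list(labels), columns=list(labels))
    per_class_f1 = pd.Series(per_class, index=list(labels), name="f1")
    return matrix, per_class_f1, float(per_class.mean())
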