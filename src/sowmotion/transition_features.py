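"""Kinematic descriptors of a segmented posture transition.

Six scalars characterise how controlled a transition was: duration, peak
acceleration magnitude, the largest single-axis acceleration range, jerk
(max |first derivative| of the magnitude series) and the maximum rates of
change of pitch and roll.  The first four are computed from the raw samples
inside the segment; the orientation rates from the preprocessed 2-s feature
frames, so they reflect posture change rather than impact transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .transition_detection import TransitionSegment, circular_diff_deg

__all__ = [
    "TransitionFeatures",
    "duration",
    "peak_acceleration",
    "acceleration_range",
    "jerk",
    "orientation_rates",
    "featurize",
    "featurize_all",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ["duration_s", "peak_accel", "accel_range", "jerk", "pitch_rate", "roll_rate"]


@dataclass(frozen=True)
class TransitionFeatures:
    duration_s: float  # time spent between posture states
    peak_accel: float  # max magnitude, g0
    accel_range: float  # largest per-axis max-min swing, g0
    jerk: float  # max |d|m|/dt|, g0/s
    pitch_rate: float  # max |dp/dt| over frames, deg/s
    roll_rate: float  # max |dr/dt| over frames, deg/s

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def duration(seg: TransitionSegment) -> float:
    """Transition duration in seconds."""
    return seg.end_s - seg.start_s


def peak_acceleration(window: np.ndarray) -> float:
    """Maximum of the magnitude series over the raw-sample window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise EmptyInputError("peak_acceleration needs at least one sample")
    return float(np.linalg.norm(w, axis=1).max())


def acceleration_range(window: np.ndarray) -> float:
    """Largest per-axis (max - min) over the window: the biggest swing in any one direction."""
    w = np.asarray(window, dtype=float)
    if w.shape[0] < 2:
        raise EmptyInputError("acceleration_range needs at least two samples")
    return float((w.max(axis=0) - w.min(axis=0)).max())


def jerk(window: np.ndarray, rate_hz: float) -> float:
    """Max |discrete first derivative| of the magnitude series, in g0/s."""
    w = np.asarray(window, dtype=float)
    if w.shape[0] < 2:
        raise EmptyInputError("jerk needs at least two samples")
    m = np.linalg.norm(w, axis=1)
    return float(np.abs(np.diff(m)).max() * rate_hz)


def orientation_rates(frames: pd.DataFrame) -> tuple[float, float]:
    """Max |frame-to-frame change| of pitch and of roll divided by the frame step (deg/s)."""
    if len(frames) < 2:
        raise EmptyInputError("orientation rates need at least two frames in the segment")
    p = frames["p"].to_numpy(dtype=float)
    r = frames["r"].to_numpy(dtype=float)
    starts = frames["start_s"].to_numpy(dtype=float)
    steps = np.diff(starts)
    pitch_rate = float(np.max(np.abs(np.diff(p)) / steps))
    roll_rate = float(np.max(circular_diff_deg(r[1:], r[:-1]) / steps))
    return pitch_rate, roll_rate


def featurize(
    seg: TransitionSegment, trace, frames: pd.DataFrame
) -> TransitionFeatures:
    """Compute all six descriptors over the segment's [start_s, end_s]."""
    rate = trace.sample_rate_hz
    i0 = max(int(np.floor(seg.start_s * rate)), 0)
    i1 = min(int(np.ceil(seg.end_s * rate)), len(trace))
    window = trace.samples[i0:i1]
    mask = (frames["start_s"] < seg.end_s) & (frames["end_s"] > seg.start_s)
    seg_frames = frames.loc[mask]
    if len(seg_frames) < 2:  # pad to the enclosing frames so rates are defined
        lo = max(int(seg.start_s // (frames["end_s"].iloc[0] - frames["start_s"].iloc[0])) - 1, 0)
        seg_frames = frames.iloc[lo : lo + 2]
    p_rate, r_rate = orientation_rates(seg_frames)
    return TransitionFeatures(
        duration_s=duration(seg),
        peak_accel=peak_acceleration(window),
        accel_range=acceleration_range(window),
        jerk=jerk(window, rate),
        pitch_rate=p_rate,
        roll_rate=r_rate,
    )


def featurize_all(
    segments: list[TransitionSegment], trace, frames: pd.DataFrame
) -> pd.DataFrame:
    """One row of descriptors per segment, plus the segment times."""
    rows = []
    for seg in segments:
        d = featurize(seg, trace, frames).as_dict()
        d.update(start_s=seg.start_s, point_s=seg.point_s, end_s=seg.end_s)
        rows.append(d)
    cols = ["start_s", "point_s", "end_s"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)
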