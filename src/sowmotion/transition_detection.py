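"""Posture-transition detection and segmentation.

Consecutive 2-s feature frames are merged into overlapping 12-s *extended*
frames.  A pair of consecutive extended frames marks a candidate transition
when the absolute change in pitch exceeds ``theta_p`` OR the absolute
(circular) change in roll exceeds ``theta_r``; the candidate is confirmed
only when neighbouring pairs also exceed a threshold, which discards brief
positional adjustments.  The emitted transition point is the midpoint
between the two frames of the first exceeding pair, and runs of consecutive
confirmed pairs collapse to a single point.

Each transition point is then segmented by walking outward over the 2-s
frames until the orientation is again consistent for at least the
stabilisation window, yielding the transition's start and end times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, IntervalError
from .features import FilterConfig, FrameConfig, _angles_from_gravity, extract_features

__all__ = [
    "DetectionConfig",
    "TransitionSegment",
    "circular_diff_deg",
    "build_extended_frames",
    "detect_transition_points",
    "segment_transition",
    "detect_and_segment",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and window parameters of the transition detector.

    ``theta_p`` / ``theta_r`` are the pitch and roll change thresholds in
    degrees.  ``group_size`` 2-s frames form one extended frame (default 6,
    i.e. 12 s) and consecutive extended frames overlap by
    ``overlap_fraction`` of their length; the realised stride is the nearest
    whole number of underlying frames (default 2 frames = 4 s).  A candidate
    pair must be accompanied by at least ``confirm_adjacent`` neighbouring
    exceeding pairs.  Stabilisation search uses ``stabilization_window_s``
    and per-angle tolerances (defaulting to a third of each threshold).
    """

    theta_p: float = 15.0
    theta_r: float = 15.0
    group_size: int = 6
    overlap_fraction: float = 0.6
    confirm_adjacent: int = 1
    stabilization_window_s: float = 1.5
    stability_tol_p: Optional[float] = None
    stability_tol_r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta_p <= 0 or self.theta_r <= 0:
            raise ConfigError("theta_p and theta_r must be positive")
        if self.group_size < 1:
            raise ConfigError("group_size must be >= 1")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if self.confirm_adjacent < 0:
            raise ConfigError("confirm_adjacent must be >= 0")

    @property
    def stride(self) -> int:
        """Extended-frame stride in underlying frames (>= 1)."""
        return max(1, round(self.group_size * (1.0 - self.overlap_fraction)))

    @property
    def tol_p(self) -> float:
        return self.stability_tol_p if self.stability_tol_p is not None else self.theta_p / 3.0

    @property
    def tol_r(self) -> float:
        return self.stability_tol_r if self.stability_tol_r is not None else self.theta_r / 3.0


@dataclass
class TransitionSegment:
    """A detected posture transition.

    ``point_s`` is the detected transition point; ``start_s``/``end_s`` the
    segmented boundaries (``start_s <= point_s <= end_s``).  ``truncated``
    marks boundaries clamped at a trace edge before stabilisation was found.
    """

    point_s: float
    start_s: float
    end_s: float
    animal_id: str = ""
    truncated: bool = False
    from_label: Optional[str] = None
    to_label: Optional[str] = None
    features: Optional[object] = None

    def __post_init__(self) -> None:
        if not (self.start_s <= self.point_s <= self.end_s) or not self.end_s > self.start_s:
            raise IntervalError(
                f"segment must satisfy start <= point <= end and start < end, got "
                f"({self.start_s}, {self.point_s}, {self.end_s})"
            )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


def circular_diff_deg(a, b) -> np.ndarray:
    """Smallest absolute angular difference in degrees (handles the ±180 wrap)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.where(d > 180.0, 360.0 - d, d)


def build_extended_frames(frames: pd.DataFrame, cfg: DetectionConfig) -> pd.DataFrame:
    """Merge consecutive 2-s frames into overlapping extended frames.

    Pitch and roll of an extended frame are recomputed from the mean gravity
    over its span (exact when the per-frame ``gx,gy,gz`` columns are present;
    otherwise unit gravity vectors are reconstructed from each frame's p, r).
    Activity is the pooled population SD of the magnitude series over the
    span when ``a`` and ``m_mean`` are available, else the RMS of the
    per-frame activities.
    """
    n = len(frames)
    if n < cfg.group_size:
        raise EmptyInputError(
            f"need at least {cfg.group_size} frames to build extended frames, got {n}"
        )
    if cfg.group_size == 1 and cfg.stride == 1:
        return frames.copy()
    starts = np.arange(0, n - cfg.group_size + 1, cfg.stride)
    if {"gx", "gy", "gz"}.issubset(frames.columns):
        gvec = frames[["gx", "gy", "gz"]].to_numpy(dtype=float)
    else:
        p = np.radians(frames["p"].to_numpy(dtype=float))
        r = np.radians(frames["r"].to_numpy(dtype=float))
        gvec = np.column_stack(
            [-np.cos(p) * np.sin(r), np.sin(p), np.cos(p) * np.cos(r)]
        )
    a = frames["a"].to_numpy(dtype=float)
    m_mean = frames["m_mean"].to_numpy(dtype=float) if "m_mean" in frames.columns else None
    start_s = frames["start_s"].to_numpy(dtype=float)
    end_s = frames["end_s"].to_numpy(dtype=float)

    rows = {k: [] for k in ("start_s", "end_s", "p", "r", "a")}
    gmeans = np.empty((len(starts), 3))
    for j, s0 in enumerate(starts):
        sl = slice(s0, s0 + cfg.group_size)
        gmeans[j] = gvec[sl].mean(axis=0)
        rows["start_s"].append(start_s[s0])
        rows["end_s"].append(end_s[s0 + cfg.group_size - 1])
        if m_mean is not None:
            # Pooled population SD over equal-length sub-frames.
            second = np.mean(a[sl] ** 2 + m_mean[sl] ** 2)
            rows["a"].append(float(np.sqrt(max(second - np.mean(m_mean[sl]) ** 2, 0.0))))
        else:
            rows["a"].append(float(np.sqrt(np.mean(a[sl] ** 2))))
    p_ext, r_ext = _angles_from_gravity(gmeans)
    rows["p"], rows["r"] = list(p_ext), list(r_ext)
    return pd.DataFrame(rows)


def detect_transition_points(ext: pd.DataFrame, cfg: DetectionConfig) -> np.ndarray:
    """Apply the threshold rule to consecutive extended frames.

    Returns an array of transition points (seconds).  A pair ``(i-1, i)`` is
    a candidate when ``|dp| > theta_p`` or ``|dr| > theta_r``; it is
    confirmed when at least ``confirm_adjacent`` of its two neighbouring
    pairs are also candidates.  Runs of consecutive confirmed pairs collapse
    to the midpoint of the run's first pair.
    """
    n = len(ext)
    if n < 2:
        raise EmptyInputError("need at least 2 extended frames for detection")
    p = ext["p"].to_numpy(dtype=float)
    r = ext["r"].to_numpy(dtype=float)
    centers = (ext["start_s"].to_numpy(dtype=float) + ext["end_s"].to_numpy(dtype=float)) / 2.0

    exceed = (np.abs(np.diff(p)) > cfg.theta_p) | (circular_diff_deg(r[1:], r[:-1]) > cfg.theta_r)
    m = len(exceed)
    confirmed = np.zeros(m, dtype=bool)
    for i in np.flatnonzero(exceed):
        neighbours = int(i > 0 and exceed[i - 1]) + int(i < m - 1 and exceed[i + 1])
        confirmed[i] = neighbours >= cfg.confirm_adjacent
    points = []
    prev = False
    for i in range(m):
        if confirmed[i] and not prev:
            points.append((centers[i] + centers[i + 1]) / 2.0)
        prev = confirmed[i]
    return np.asarray(points, dtype=float)


def segment_transition(
    frames: pd.DataFrame, point_s: float, cfg: DetectionConfig
) -> TransitionSegment:
    """Find transition boundaries by outward stabilisation search.

    Walking outward from the frame containing ``point_s``, each side's
    boundary is placed at the edge of the first pair of consecutive 2-s
    frames whose pitch and roll agree within the stability tolerances (one
    stable pair spans at least the stabilisation window).  If no stable pair
    exists before the trace edge, the edge is used and the segment flagged
    ``truncated``.
    """
    start_s = frames["start_s"].to_numpy(dtype=float)
    end_s = frames["end_s"].to_numpy(dtype=float)
    if not (start_s[0] <= point_s <= end_s[-1]):
        raise IntervalError(
            f"transition point {point_s}s outside frame coverage "
            f"[{start_s[0]}, {end_s[-1]}]s"
        )
    p = frames["p"].to_numpy(dtype=float)
    r = frames["r"].to_numpy(dtype=float)
    n = len(frames)
    frame_len = end_s[0] - start_s[0]

    def stable(j: int) -> bool:
        # Orientation consistent across frames j-1 and j.
        return (
            abs(p[j] - p[j - 1]) <= cfg.tol_p
            and circular_diff_deg(r[j], r[j - 1]) <= cfg.tol_r
        )

    i0 = min(int(np.searchsorted(end_s, point_s, side="left")), n - 1)

    truncated = False
    left = None
    for j in range(i0, 0, -1):  # pair (j-1, j), walking left
        if stable(j):
            left = end_s[j]
            break
    if left is None:
        left = start_s[0]
        truncated = True

    right = None
    for j in range(i0 + 1, n):  # pair (j-1, j), walking right
        if stable(j):
            right = start_s[j - 1]
            break
    if right is None:
        right = end_s[-1]
        truncated = True

    # Guarantee start < point < end (a step exactly at a frame edge can
    # collapse both boundaries onto the point): pad by half a frame.
    if left >= point_s:
        left = max(start_s[0], point_s - frame_len / 2.0)
    if right <= point_s:
        right = min(end_s[-1], point_s + frame_len / 2.0)
    return TransitionSegment(point_s=point_s, start_s=left, end_s=right, truncated=truncated)


def detect_and_segment(
    trace,
    fcfg: FilterConfig | None = None,
    wcfg: FrameConfig | None = None,
    dcfg: DetectionConfig | None = None,
) -> list[TransitionSegment]:
    """Full detection pipeline: features -> extended frames -> points -> segments.

    Overlapping segments arising from nearby points are merged (interval
    union; the first point is kept).  The result is time-ordered and
    non-overlapping.
    """
    dcfg = dcfg or DetectionConfig()
    frames = extract_features(trace, fcfg, wcfg)
    if len(frames) < max(dcfg.group_size, 2):
        return []
    ext = build_extended_frames(frames, dcfg)
    if len(ext) < 2:
        return []
    points = detect_transition_points(ext, dcfg)
    segments = [segment_transition(frames, pt, dcfg) for pt in points]
    merged: list[TransitionSegment] = []
    for seg in segments:
        seg.animal_id = getattr(trace, "animal_id", "")
        if merged and seg.start_s < merged[-1].end_s:
            last = merged[-1]
            last.end_s = max(last.end_s, seg.end_s)
            last.truncated = last.truncated or seg.truncated
        else:
            merged.append(seg)
    return merged


def segments_to_frame(segments: list[TransitionSegment]) -> pd.DataFrame:
    """Tabulate segments as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in segments],
            "start_s": [s.start_s for s in segments],
            "point_s": [s.point_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "truncated": [s.truncated for s in segments],
        }
    )
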