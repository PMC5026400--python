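"""Trace and annotation data model plus plain-text (CSV) I/O.

The on-disk trace format is a CSV with ``# key=value`` metadata header lines
(``rate_hz``, ``animal_id``) followed by columns ``time_s,x,y,z`` (the time
column is optional).  Axis conventions follow the hind-end sensor mounting:
x is craniocaudal, y mediolateral, z dorsoventral.  Values are accelerations
in g0 units within the sensor range of +/-8 g0; out-of-range values are
clipped (sensor-saturation behaviour) and counted in a warning.

Annotations are CSVs with columns ``track,label,start_s,end_s`` where
``track`` is ``posture`` or ``transition``.  Posture labels are the five
mutually exclusive classes ST, S, LL, RL, SL; kneeling is a transitory
posture and has no class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    IntervalError,
    LabelError,
    OverlapError,
    SamplingError,
)

__all__ = [
    "POSTURE_LABELS",
    "SENSOR_RANGE_G",
    "SignalTrace",
    "AnnotationTrack",
    "read_trace",
    "write_trace",
    "read_annotations",
    "write_annotations",
]

#: The five mutually exclusive posture classes: standing, sitting, left
#: lateral lie, right lateral lie, sternal lie.
POSTURE_LABELS = ("ST", "S", "LL", "RL", "SL")

#: Sensor measurement range in g0 units.
SENSOR_RANGE_G = 8.0

#: Relative tolerance on timestamp uniformity before a SamplingError.
_TIME_RTOL = 0.01


@dataclass
class SignalTrace:
    """A uniformly sampled tri-axial acceleration series.

    Sample ``k`` is at time ``k / sample_rate_hz`` seconds from trace start.
    """

    samples: np.ndarray  # (n, 3) float array, g0 units
    sample_rate_hz: float
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(f"samples must be (n, 3), got {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise EmptyInputError("a trace must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise SamplingError(f"sample rate must be positive, got {self.sample_rate_hz}")
        if np.any(np.abs(self.samples) > SENSOR_RANGE_G):
            raise FormatError(
                f"acceleration values outside +/-{SENSOR_RANGE_G} g0; "
                "clip on read or construct with clipped values"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def duration_h(self) -> float:
        return len(self) / (self.sample_rate_hz * 3600.0)

    @property
    def t(self) -> np.ndarray:
        """Per-sample times in seconds from trace start."""
        return np.arange(len(self)) / self.sample_rate_hz

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]


def _check_intervals(intervals, what: str, check_labels: bool) -> list:
    out = []
    for iv in intervals:
        if check_labels:
            start, end, label = float(iv[0]), float(iv[1]), str(iv[2])
            if label not in POSTURE_LABELS:
                raise LabelError(
                    f"unknown posture label {label!r}; expected one of {POSTURE_LABELS} "
                    "(kneeling is transitory and has no class)"
                )
            out.append((start, end, label))
        else:
            start, end = float(iv[0]), float(iv[1])
            out.append((start, end))
        if not start < end:
            raise IntervalError(f"{what} interval must have start < end, got ({start}, {end})")
    out.sort(key=lambda iv: iv[0])
    for prev, cur in zip(out, out[1:]):
        if cur[0] < prev[1] - 1e-9:
            raise OverlapError(f"overlapping {what} intervals: {prev} and {cur}")
    return out


@dataclass
class AnnotationTrack:
    """Ground-truth labelled intervals (postures and transitions) for one animal.

    Posture intervals are ``(start_s, end_s, label)`` triples; transition
    intervals are ``(start_s, end_s)`` pairs.  Within each track, intervals
    are non-overlapping and stored time-sorted.
    """

    animal_id: str = ""
    posture_intervals: list = field(default_factory=list)
    transition_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.posture_intervals = _check_intervals(
            self.posture_intervals, "posture", check_labels=True
        )
        self.transition_intervals = _check_intervals(
            self.transition_intervals, "transition", check_labels=False
        )

    def shifted(self, offset_s: float) -> "AnnotationTrack":
        """Return a copy with all interval times shifted by a constant offset."""
        return AnnotationTrack(
            animal_id=self.animal_id,
            posture_intervals=[(s + offset_s, e + offset_s, l) for s, e, l in self.posture_intervals],
            transition_intervals=[(s + offset_s, e + offset_s) for s, e in self.transition_intervals],
        )


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_trace(path, rate: float | None = None) -> SignalTrace:
    """Read a trace CSV.

    The file's ``# rate_hz=`` metadata takes precedence; otherwise ``rate``
    must be supplied.  A ``time_s`` column, when present, is checked for
    uniformity against the rate.  Values outside the sensor range are
    clipped with a warning reporting the count.
    """
    path = Path(path)
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    if df.empty:
        raise EmptyInputError(f"{path} contains no samples")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"{path} is missing required columns {sorted(missing)}")

    if "rate_hz" in meta:
        rate_hz = float(meta["rate_hz"])
    elif rate is not None:
        rate_hz = float(rate)
    else:
        raise SamplingError(f"{path} has no rate_hz metadata and no rate was given")

    if "time_s" in df.columns and len(df) > 1:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(np.abs(dt * rate_hz - 1.0) > _TIME_RTOL):
            raise SamplingError(
                f"{path}: timestamps deviate from uniform sampling at {rate_hz} Hz"
            )

    values = df[["x", "y", "z"]].to_numpy(dtype=float)
    n_clip = int(np.count_nonzero(np.abs(values) > SENSOR_RANGE_G))
    if n_clip:
        warnings.warn(
            f"{path}: clipped {n_clip} values outside +/-{SENSOR_RANGE_G} g0",
            stacklevel=2,
        )
        values = np.clip(values, -SENSOR_RANGE_G, SENSOR_RANGE_G)
    return SignalTrace(values, rate_hz, animal_id=meta.get("animal_id", ""))


def write_trace(trace: SignalTrace, path, include_time: bool = True) -> None:
    """Write a trace CSV readable by :func:`read_trace` (round-trip to 6 d.p.)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={trace.sample_rate_hz!r}\n")
        if trace.animal_id:
            fh.write(f"# animal_id={trace.animal_id}\n")
        cols = ["time_s", "x", "y", "z"] if include_time else ["x", "y", "z"]
        fh.write(",".join(cols) + "\n")
        data = trace.samples
        if include_time:
            data = np.column_stack([trace.t, data])
        np.savetxt(fh, data, fmt="%.6f", delimiter=",")


def read_annotations(path) -> AnnotationTrack:
    """Read an annotation CSV with columns ``track,label,start_s,end_s``."""
    path = Path(path)
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    missing = {"track", "label", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise FormatError(f"{path} is missing required columns {sorted(missing)}")
    postures, transitions = [], []
    for row in df.itertuples(index=False):
        track = str(row.track).strip().lower()
        if track == "posture":
            postures.append((float(row.start_s), float(row.end_s), str(row.label).strip()))
        elif track == "transition":
            transitions.append((float(row.start_s), float(row.end_s)))
        else:
            raise FormatError(f"{path}: unknown track {row.track!r}")
    return AnnotationTrack(
        animal_id=meta.get("animal_id", ""),
        posture_intervals=postures,
        transition_intervals=transitions,
    )


def write_annotations(track: AnnotationTrack, path) -> None:
    """Write an annotation CSV readable by :func:`read_annotations`."""
    path = Path(path)
    with open(path, "w") as fh:
        if track.animal_id:
            fh.write(f"# animal_id={track.animal_id}\n")
        fh.write("track,label,start_s,end_s\n")
        for start, end, label in track.posture_intervals:
            fh.write(f"posture,{label},{start:.6f},{end:.6f}\n")
        for start, end in track.transition_intervals:
            fh.write(f"transition,,{start:.6f},{end:.6f}\n")
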