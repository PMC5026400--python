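"""Per-animal lying-behaviour profiles.

Three summaries describe how a sow lies over the observation period: a
posture *time budget* (proportion of classified frames per posture), a
*transition-frequency* series (number of transitions in each 2-h window
stepped by 12 min — the nest-building surge before farrowing shows up as a
spike), and, for each transition descriptor, the animal's empirical
cumulative distribution function (ECDF) next to the baseline ECDF pooled
over all animals' transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .sensor_io import POSTURE_LABELS
from .transition_features import FEATURE_NAMES

__all__ = ["ECDF", "BehaviourProfile", "time_budget", "transition_frequency", "ecdf", "profile"]


class ECDF:
    """Right-continuous empirical CDF: F(x) = #{v <= x} / n."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise EmptyInputError("ECDF needs at least one value")
        self._sorted = np.sort(v)

    @property
    def n(self) -> int:
        return self._sorted.size

    @property
    def values(self) -> np.ndarray:
        return self._sorted

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self._sorted, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def ecdf(values) -> ECDF:
    """Build the ECDF step function of a sample."""
    return ECDF(values)


@dataclass
class BehaviourProfile:
    animal_id: str
    time_budget: pd.Series  # proportion per posture, sums to 1
    transition_frequency: pd.DataFrame  # window_center_s, count
    ecdf_per_feature: dict = field(default_factory=dict)  # name -> (animal ECDF, baseline ECDF)
    flags: list = field(default_factory=list)


def time_budget(labels) -> pd.Series:
    """Proportion of frames per posture class, in fixed class order."""
    labs = pd.Series(list(labels))
    if labs.empty:
        raise EmptyInputError("time budget needs at least one label")
    counts = labs.value_counts()
    budget = pd.Series(
        [counts.get(lab, 0) / len(labs) for lab in POSTURE_LABELS],
        index=list(POSTURE_LABELS),
        name="proportion",
    )
    return budget


def transition_frequency(
    points_s, trace_span_s: float, window_s: float = 7200.0, step_s: float = 720.0
) -> pd.DataFrame:
    """Count transitions in each [start, start+window) position stepped by ``step_s``.

    Only full windows inside the span are emitted; a span shorter than one
    window yields a single truncated window (flagged).  Counts are reported
    at window-centre timestamps.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    pts = np.sort(np.asarray(points_s, dtype=float))
    if trace_span_s < window_s:
        warnings.warn("span shorter than one window; emitting a truncated window", stacklevel=2)
        count = int(np.count_nonzero((pts >= 0) & (pts < trace_span_s)))
        return pd.DataFrame(
            {"window_center_s": [trace_span_s / 2.0], "count": [count], "truncated": [True]}
        )
    starts = np.arange(0.0, trace_span_s - window_s + 1e-9, step_s)
    lo = np.searchsorted(pts, starts, side="left")
    hi = np.searchsorted(pts, starts + window_s, side="left")
    return pd.DataFrame(
        {
            "window_center_s": starts + window_s / 2.0,
            "count": (hi - lo).astype(int),
            "truncated": False,
        }
    )


def profile(
    animals: dict,
    window_s: float = 7200.0,
    step_s: float = 720.0,
    leave_one_out_baseline: bool = False,
) -> dict:
    """Build one BehaviourProfile per animal.

    Parameters
    ----------
    animals : dict
        ``animal_id -> dict`` with keys ``labels`` (posture labels per
        frame), ``transition_features`` (DataFrame with the six descriptor
        columns and ``point_s``), and ``span_s`` (trace span in seconds).
    leave_one_out_baseline : bool
        When True the baseline ECDF for an animal excludes that animal's
        own transitions; by default the baseline pools every animal
        (including the one under comparison).
    """
    if not animals:
        raise EmptyInputError("profile needs at least one animal")
    pooled = {
        name: np.concatenate(
            [
                np.asarray(d["transition_features"][name], dtype=float)
                for d in animals.values()
                if len(d["transition_features"])
            ]
        )
        if any(len(d["transition_features"]) for d in animals.values())
        else np.array([])
        for name in FEATURE_NAMES
    }
    out = {}
    for animal_id, d in animals.items():
        tf = d["transition_features"]
        flags = []
        prof = BehaviourProfile(
            animal_id=animal_id,
            time_budget=time_budget(d["labels"]),
            transition_frequency=transition_frequency(
                np.asarray(tf["point_s"], dtype=float) if len(tf) else np.array([]),
                d["span_s"],
                window_s,
                step_s,
            ),
            flags=flags,
        )
        if len(tf) == 0:
            flags.append("no transitions: ECDFs omitted")
        else:
            for name in FEATURE_NAMES:
                own = np.asarray(tf[name], dtype=float)
                base = pooled[name]
                if leave_one_out_baseline:
                    others = [
                        np.asarray(o["transition_features"][name], dtype=float)
                        for aid, o in animals.items()
                        if aid != animal_id and len(o["transition_features"])
                    ]
                    base = np.concatenate(others) if others else own
                prof.ecdf_per_feature[name] = (ecdf(own), ecdf(base))
        out[animal_id] = prof
    return out
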