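"""Exception hierarchy for sowmotion.

All package errors derive from :class:`SowMotionError` so callers (and the
CLI) can distinguish validation failures from programming errors.
"""


class SowMotionError(Exception):
    """Base class for all sowmotion errors."""


class FormatError(SowMotionError):
    """A file does not conform to the expected columnar layout."""


class EmptyInputError(SowMotionError):
    """An input that must contain data is empty."""


class SamplingError(SowMotionError):
    """Timestamps are inconsistent with uniform sampling at the stated rate."""


class IntervalError(SowMotionError):
    """An annotation interval is degenerate (start >= end) or out of range."""


class LabelError(SowMotionError):
    """A posture label is not one of the five recognised classes."""


class OverlapError(SowMotionError):
    """Intervals within a single annotation track overlap."""


class OrientationError(SowMotionError):
    """Pitch/roll are undefined for the given gravity vector."""


class UndefinedMetricError(SowMotionError):
    """A ratio metric has a zero denominator (e.g. no detections at all)."""


class ConfigError(SowMotionError):
    """A configuration value violates its invariants."""


class PipelineError(SowMotionError):
    """A pipeline stage failed; the message names the stage."""
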