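"""Exception hierarchy for the TUG analysis pipeline.

Every stage raises a subclass of :class:`TugError`, so callers can catch a
single type and still report which stage failed (the CLI maps subclasses to
exit codes).
"""


class TugError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TugError):
    """A keypoint or cohort file is malformed (missing fps, resolution, ...)."""


class SchemaError(TugError):
    """A required joint or feature is absent or unmappable."""


class PairingError(TugError):
    """Paired 2D/3D streams disagree (frame counts, lengths)."""


class ParameterError(TugError):
    """An invalid analysis parameter (cutoff above Nyquist, bad window...)."""


class EmptySignalError(TugError):
    """A signal is empty or all-NaN."""


class CalibrationError(TugError):
    """Self-calibration could not run or did not converge."""


class HorizonError(TugError):
    """A ground-plane back-projection ray does not intersect the floor."""


class DegenerateGeometryError(TugError):
    """Geometry too close to a singular configuration (subject under camera)."""


class DegeneratePriorError(TugError):
    """The scale-ambiguous depth prior carries no variance to align."""


class SegmentationError(TugError):
    """Phase segmentation failed (missing postural change, missing turns)."""


class StateMachineError(SegmentationError):
    """Detected events violate the TUG phase ordering."""


class UndefinedStatisticError(TugError):
    """A statistic is undefined for the available events (e.g. CV of 0 steps)."""


class ConfigError(TugError):
    """An inconsistent simulator or pipeline configuration."""


class EvaluationError(TugError):
    """Cross-validated evaluation could not be completed (degenerate fold)."""
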