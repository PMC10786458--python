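"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`NucleostrainError` so callers can
catch pipeline failures without masking programming errors.
"""


class NucleostrainError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(NucleostrainError, ValueError):
    """A phantom or run specification violates its invariants."""


class CalibrationError(NucleostrainError, ValueError):
    """Dye calibration is ill-conditioned (e.g. temperature span too small)."""


class InvalidReferenceError(NucleostrainError, ValueError):
    """Reference intensity for thermometry is non-positive."""


class SegmentationError(NucleostrainError, ValueError):
    """Segmentation produced an empty or degenerate mask."""


class PIVConfigError(NucleostrainError, ValueError):
    """PIV configuration incompatible with the input frames."""


class FitError(NucleostrainError, RuntimeError):
    """Nonlinear fit failed to converge."""


class StageError(NucleostrainError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
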