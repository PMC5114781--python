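"""Exception hierarchy for the renovol pipeline.

Every error raised by the package derives from :class:`RenovolError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class RenovolError(Exception):
    """Base class for all renovol errors."""


class HeaderError(RenovolError):
    """NIfTI header is unusable (non-positive voxel size, NaN payload, ...)."""


class DimensionalityError(RenovolError):
    """Input volume is not 3-D (and not squeezable to 3-D)."""


class AlignmentError(RenovolError):
    """Image and mask do not share the same voxel grid."""


class EmptyROIError(RenovolError):
    """The ROI mask contains no foreground voxel."""


class DegenerateSampleError(RenovolError):
    """Intensity sample too small or constant to estimate a density from."""


class ConfigurationError(RenovolError):
    """A tuning parameter is outside its valid range."""


class NoPeakError(RenovolError):
    """The estimated PDF has no interior local maximum."""


class PeakSelectionError(RenovolError):
    """User-chosen peak ordinal does not index a detected peak."""


class DegenerateChordError(RenovolError):
    """Chord endpoint collapses onto the peak (sigma below one grid step)."""


class CornerNotFoundError(RenovolError):
    """No grid point lies strictly below the chord line on the given side."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"no corner found on the {side} side")


class ExportError(RenovolError):
    """Results destination exists with an incompatible schema."""


class PhantomSpecError(RenovolError):
    """Phantom specification is internally inconsistent or infeasible."""
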