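"""Exception hierarchy for the pipeline.

Every stage raises a distinct subclass of :class:`CTEdemaError` so the CLI can
name the failing stage in its exit message.
"""


class CTEdemaError(Exception):
    """Base class for all pipeline errors."""


class LoadError(CTEdemaError):
    """A volume or mask could not be loaded, or violated a load-time invariant."""


class GridMismatchError(CTEdemaError):
    """A mask does not share its parent volume's shape/affine."""


class SegmentationFailureError(CTEdemaError):
    """Intracranial segmentation found no plausible brain component."""


class SymmetryFailureError(CTEdemaError):
    """Symmetry-plane search failed to find a plausible mid-sagittal plane."""


class OutOfFieldError(CTEdemaError):
    """A mirrored mask falls substantially outside the volume's field of view."""


class EmptyROIError(CTEdemaError):
    """A density ROI is empty after masking/filtering."""


class NonPhysicalDensityError(CTEdemaError):
    """Reference (contralateral) density is non-positive."""


class DegenerateInputError(CTEdemaError):
    """A statistical routine received degenerate input (e.g. all-zero differences)."""


class SeparationError(CTEdemaError):
    """Logistic regression detected (quasi-)complete separation."""


class SpecError(CTEdemaError):
    """A synthetic-data specification is internally inconsistent."""
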