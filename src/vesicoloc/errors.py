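"""Exception hierarchy for the vesicoloc pipeline.

Every failure mode the pipeline can report maps onto one of these, so callers
(and the CLI) can distinguish bad calibration from bad geometry from bad
parameters without string-matching messages.
"""


class VesicolocError(Exception):
    """Base class for all vesicoloc errors."""


class CalibrationError(VesicolocError):
    """Physical calibration (pixel size, z spacing) missing or invalid."""


class AnnotationError(VesicolocError):
    """Acquisition annotations (channel labels, sidecar rows) inconsistent."""


class ValidationError(VesicolocError):
    """Image data violates an invariant (non-finite, negative, wrong shape)."""


class ParameterError(VesicolocError):
    """Analysis parameters out of their admissible range."""


class GeometryError(VesicolocError):
    """Shape/geometry mismatch between images, masks, or line coordinates."""


class DegenerateInputError(VesicolocError):
    """Input is formally valid but carries no usable signal (empty region,
    no positive filtered values, group too small for a test)."""
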