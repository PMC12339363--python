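"""Exception hierarchy for the package."""


class VatmapError(Exception):
    """Base class for all package errors."""


class ParameterError(VatmapError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(VatmapError, ValueError):
    """A file could not be parsed, or violates a container invariant."""


class UnsupportedGeometryError(VatmapError, ValueError):
    """A volume is not on an isotropic, axis-aligned grid."""


class OutOfBoundsError(VatmapError, ValueError):
    """A coordinate or sphere falls entirely outside the grid."""


class ResolutionError(VatmapError, ValueError):
    """The grid is too coarse for the requested operation."""


class ValidationError(VatmapError, ValueError):
    """A table is incomplete or inconsistent."""


class DegeneratePredictorError(VatmapError, ValueError):
    """The regression predictor has zero variance."""


class DegenerateFoldError(VatmapError, ValueError):
    """A leave-one-out training subset has zero predictor variance."""


class InsufficientDataError(VatmapError, ValueError):
    """Fewer observations than the statistic requires."""


class GeometryError(VatmapError, ValueError):
    """Two volumes that must share a grid do not."""
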