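"""Exception hierarchy shared by all palatometry modules."""


class PalatometryError(Exception):
    """Base class for all errors raised by this package."""


class MetadataError(PalatometryError):
    """Volume metadata is missing or invalid (e.g. zero spacing)."""


class FormatError(PalatometryError):
    """A file could not be parsed in the requested format."""


class ParameterError(PalatometryError, ValueError):
    """A parameter is outside its documented range."""


class EmptyMaskError(PalatometryError):
    """An operation that needs foreground voxels received an empty mask."""


class EmptySurfaceError(PalatometryError):
    """No iso-surface crossing exists in the volume."""


class EmptyResultError(PalatometryError):
    """A crop or selection retained nothing."""


class GeometryError(PalatometryError):
    """Degenerate or self-intersecting geometry."""


class FitFailureError(PalatometryError):
    """Surface fitting did not converge to an acceptable residual."""


class InsufficientSupportError(PalatometryError):
    """Too few support samples around a defect to constrain a patch."""


class ConsistencyError(PalatometryError):
    """Mutually inconsistent quantities (e.g. cleft area > total area)."""
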