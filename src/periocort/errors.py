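"""Exception and warning types shared across the package."""


class PeriocortError(Exception):
    """Base class for all errors raised by periocort."""


class UnsupportedImageError(PeriocortError):
    """Raised for color, floating-point or otherwise unsupported rasters."""


class RoiBoundsError(PeriocortError):
    """Raised when an ROI geometry extends outside the image."""


class EmptyRoiError(PeriocortError):
    """Raised when an ROI geometry resolves to zero pixels."""


class SchemaError(PeriocortError):
    """Raised when a cohort or feature table violates the documented schema."""


class InsufficientExtentError(PeriocortError):
    """Raised when an ROI admits no pixel pair at the requested offset."""


class InsufficientDataError(PeriocortError):
    """Raised when a statistical routine receives too few observations."""


class ParameterError(PeriocortError):
    """Raised for invalid generator or configuration parameters."""


class RoiSizeWarning(UserWarning):
    """ROI does not contain the 1500 pixels of the acquisition protocol."""


class UndefinedCIWarning(UserWarning):
    """Corticalization index undefined (zero difference entropy)."""
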