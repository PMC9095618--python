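"""Exception types shared across the package."""


class MCFHoloError(Exception):
    """Base class for all package errors."""


class GeometryError(MCFHoloError, ValueError):
    """Invalid grid geometry (non-positive pitch/wavelength, size mismatch, ...)."""


class PackingError(MCFHoloError, RuntimeError):
    """Core placement could not satisfy the spacing/facet constraints."""


class OutOfBoundsError(MCFHoloError, ValueError):
    """A core center falls outside the sampling grid."""


class ConstantImageError(MCFHoloError, ValueError):
    """Correlation requested on a zero-variance image."""


class ConfigError(MCFHoloError, ValueError):
    """Invalid network/training configuration."""


class FileFormatError(MCFHoloError, ValueError):
    """Malformed core-map / checkpoint / image file."""
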