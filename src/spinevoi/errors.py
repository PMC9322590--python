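"""Exception hierarchy shared across the package."""


class SpineVoiError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpineVoiError):
    """A configuration object violates its invariants."""


class SizingError(ConfigError):
    """Requested phantom geometry does not fit the voxel grid."""


class InvalidInputError(SpineVoiError):
    """An operation received an empty or malformed input volume."""


class DegenerateGeometryError(SpineVoiError):
    """A morphological step annihilated its input (structure too thin)."""


class MissingVoiError(SpineVoiError):
    """A VOI that a metric computation needs is empty or absent."""


class ParameterError(SpineVoiError):
    """A scalar parameter is outside its physical domain."""


class DegenerateVarianceError(SpineVoiError):
    """Paired differences are all identical; no test statistic exists."""


class InsufficientDataError(SpineVoiError):
    """Fewer pairs than the minimum needed for inference."""


class VolumeFormatError(SpineVoiError):
    """A volume file is not a 3-D image with positive voxel spacings."""
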