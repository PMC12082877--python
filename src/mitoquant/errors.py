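"""Exception hierarchy for mitoquant."""


class MitoquantError(Exception):
    """Base class for all package errors."""


class ConfigError(MitoquantError):
    """Invalid configuration values."""


class PlacementError(MitoquantError):
    """An object could not be placed inside the simulated field."""


class DegenerateImageError(MitoquantError):
    """Image has no intensity structure (e.g. constant) where structure is required."""


class CalibrationError(MitoquantError):
    """Line-profile calibration found no usable peak."""


class ColocError(MitoquantError):
    """Colocalization statistic is undefined on the given input."""


class DesignError(MitoquantError):
    """Experimental design is insufficient for the requested model."""


class FitError(MitoquantError):
    """Model fitting failed or is non-identifiable."""
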