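"""Exception hierarchy shared across the package."""


class SpequantError(Exception):
    """Base class for all package-specific errors."""


class DesignSizeError(SpequantError, ValueError):
    """Requested factor count does not fit the run count of any supported design."""


class PlanError(SpequantError, ValueError):
    """An experimental-plan table could not be parsed or is internally inconsistent."""


class IncompleteDataError(SpequantError, ValueError):
    """A required response or replicate value is missing."""


class FitError(SpequantError, ValueError):
    """A regression could not be computed (e.g. rank-deficient design)."""


class CalibrationError(SpequantError, ValueError):
    """Calibration data or parameters are unusable (too few levels, bad slope...)."""


class ConfigurationError(SpequantError, ValueError):
    """A configuration, template or generator parameter is invalid."""


class DataError(SpequantError, ValueError):
    """Observed data violate a physical precondition (negative intensity, zero mean...)."""
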