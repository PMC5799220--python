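"""Exception hierarchy shared across the package."""


class FaupaError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FaupaError, ValueError):
    """An algorithm or filter parameter is outside its valid range."""


class GeometryError(FaupaError, ValueError):
    """Array shapes or grid definitions are mutually inconsistent."""


class DegenerateSeriesError(FaupaError, ValueError):
    """A time series has zero variance, so a correlation or t statistic
    is undefined for it."""


class PlacementError(FaupaError, RuntimeError):
    """Requested synthetic clusters could not be packed into the grid."""


class CalibrationError(FaupaError, RuntimeError):
    """Noise calibration failed to bracket or reach the target."""
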