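"""Exception hierarchy shared across the package."""


class SpiralfoilError(Exception):
    """Base class for all package errors."""


class GeometryError(SpiralfoilError, ValueError):
    """Invalid or inconsistent geometric specification."""


class PlacementError(GeometryError):
    """A solid placed (partly) outside the channel."""


class FlowSolverError(SpiralfoilError, RuntimeError):
    """The flow solve failed to converge or the geometry is infeasible."""


class OutOfDomainError(SpiralfoilError, ValueError):
    """A query point lies outside the fluid region."""


class FitError(SpiralfoilError, RuntimeError):
    """Nonlinear fit did not converge."""


class UndefinedMetricError(SpiralfoilError, ZeroDivisionError):
    """A performance metric has a zero denominator."""


class TransportQualityError(SpiralfoilError, RuntimeError):
    """Too much particle weight failed to reach an outlet."""


class ConfigError(SpiralfoilError, ValueError):
    """Malformed run configuration."""
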