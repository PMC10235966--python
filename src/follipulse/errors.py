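"""Exception hierarchy shared across the package.

Everything user-facing derives from :class:`FollipulseError` so callers (and the
CLI) can distinguish bad input from internal failures with one ``except``.
"""


class FollipulseError(Exception):
    """Base class for all errors raised by follipulse."""


class ValidationError(FollipulseError):
    """Input data violates a documented precondition."""


class ParameterError(ValidationError):
    """Simulation or analysis parameters are inconsistent."""


class InsufficientDataError(ValidationError):
    """Too few samples to run the requested operation."""


class DegenerateInputError(ValidationError):
    """Input is constant or otherwise carries no usable signal."""


class FitError(FollipulseError):
    """A model fit failed (no admissible contact point, negative modulus, ...)."""


class MapQualityError(FitError):
    """More than half of the points in a force map failed to fit."""


class ConfigError(FollipulseError):
    """A scenario file references unknown keys or misses required ones."""
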