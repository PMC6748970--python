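"""Exception types raised across the pipeline."""


class DriverBurdenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DriverBurdenError, ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(DriverBurdenError, ValueError):
    """A field value violates a domain invariant (range, enum, uniqueness)."""


class BalanceError(ValidationError):
    """A calibration set departs from 50:50 class balance beyond tolerance."""


class ConfigurationError(DriverBurdenError, ValueError):
    """An inconsistent model or analysis configuration."""


class CalibrationStateError(DriverBurdenError, RuntimeError):
    """An operation needs calibration state (posteriors) that is absent or undefined."""


class FdrNotAchievableError(DriverBurdenError, RuntimeError):
    """No threshold on the grid sustains the requested false discovery rate."""
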