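"""Exception hierarchy shared by all pipeline stages."""


class WearMotionError(Exception):
    """Base class for all package errors."""


class ValidationError(WearMotionError, ValueError):
    """Input violates a documented precondition or format contract."""


class StreamFormatError(ValidationError):
    """A CSV stream row or header could not be validated; names the row."""


class DegenerateInputError(WearMotionError, ValueError):
    """Numerically degenerate input (e.g. a zero-norm accelerometer sample)."""


class NumericalError(WearMotionError, ArithmeticError):
    """A numerical operation failed (e.g. singular innovation covariance)."""
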