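"""Exception hierarchy.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2);
every other :class:`FlysleepmemError` is a runtime failure (exit code 1).
"""


class FlysleepmemError(Exception):
    """Base class for all package errors."""


class ValidationError(FlysleepmemError, ValueError):
    """Invalid input data, parameters or configuration."""


class UndefinedSIError(FlysleepmemError, ArithmeticError):
    """Suppression index is undefined (naive-group center is zero)."""


class ZeroVarianceError(FlysleepmemError, ArithmeticError):
    """A statistic requiring variance was asked of constant data."""
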