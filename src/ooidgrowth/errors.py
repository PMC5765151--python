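"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`OoidError`,
so callers (and the CLI) can distinguish model/domain failures from bugs.
Most subclasses also derive from ``ValueError`` for ergonomic catching.
"""


class OoidError(Exception):
    """Base class for all errors raised by ooidgrowth."""


class ParameterError(OoidError, ValueError):
    """Invalid or out-of-regime model parameters."""


class DomainError(OoidError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DataError(OoidError, ValueError):
    """Observed data violates a structural precondition."""


class NumericalError(OoidError, ArithmeticError):
    """A numerical routine produced a non-finite or inconsistent result."""


class GenerationError(OoidError, RuntimeError):
    """Synthetic-data generation could not satisfy its own invariants."""


class ConfigError(OoidError, ValueError):
    """Configuration file or override problem; names the offending key."""
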