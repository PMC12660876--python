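"""Package-wide exception types."""


class ProbcodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProbcodeError, ValueError):
    """A configuration object violates one of its invariants.

    The message names the violated constraint.
    """


class NumericalError(ProbcodeError, ArithmeticError):
    """A computation became degenerate (e.g. an all-zero posterior row)."""


class DomainError(ProbcodeError, ValueError):
    """An input lies outside the mathematical domain of an operation."""
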