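"""Exception hierarchy used across the toolkit."""


class PopgenError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PopgenError):
    """Malformed or inconsistent input file."""


class EmptyInputError(PopgenError):
    """Input contained no usable records."""


class EmptyOutputError(PopgenError):
    """An operation would return an empty result where that is an error."""


class PreconditionError(PopgenError):
    """A documented precondition of an operation was violated."""


class InsufficientDataError(PopgenError):
    """Not enough observations to compute the requested statistic."""


class DomainError(PopgenError, ValueError):
    """Numeric argument outside the mathematical domain of the operation."""


class UndefinedStatisticError(PopgenError):
    """The statistic is undefined for this input (e.g. too few carriers)."""
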