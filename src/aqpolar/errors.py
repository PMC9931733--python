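"""Exception hierarchy shared across the pipeline stages."""


class AqpolarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AqpolarError, ValueError):
    """A parameter, marker gene, or threshold is inconsistent with the data."""


class FormatError(AqpolarError, ValueError):
    """An input file violates its format contract; the message names the file."""


class GenerationError(AqpolarError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""


class InvalidInputError(AqpolarError, ValueError):
    """Numeric input outside the domain of a statistical routine."""


class UndefinedStatisticError(AqpolarError, ArithmeticError):
    """The requested statistic is undefined for this input (0/0 ratio, zero variance)."""
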