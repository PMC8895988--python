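"""Exception types shared across the package."""


class PhenopredError(Exception):
    """Base class for package errors."""


class ParseError(PhenopredError):
    """A file could not be parsed; the message names the offending line."""


class DimensionError(PhenopredError):
    """Inconsistent table dimensions (e.g. a ragged genotype matrix)."""


class SchemaError(PhenopredError):
    """Required columns missing or of the wrong type."""


class IntegrityError(PhenopredError):
    """Duplicate keys or otherwise inconsistent table content."""


class ConfigError(PhenopredError):
    """Invalid simulation or scheme configuration."""


class DesignError(PhenopredError):
    """An experimental design that the model cannot accommodate."""


class ConvergenceError(PhenopredError):
    """REML optimisation failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class UndefinedStatisticError(PhenopredError):
    """A statistic (heritability, correlation) is undefined for the input."""
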