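"""Exception hierarchy shared across the package.

All errors raised by cernascreen derive from :class:`CernaScreenError`
so that callers (in particular the CLI) can distinguish input and
configuration problems from genuine bugs.
"""


class CernaScreenError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CernaScreenError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(CernaScreenError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class InvalidDesignError(InvalidInputError):
    """The sample-to-group design is unusable (e.g. a group with < 2 samples)."""


class InvalidConfigError(CernaScreenError, ValueError):
    """A configuration document is inconsistent or out of range."""


class PipelineError(CernaScreenError, RuntimeError):
    """A pipeline stage produced an unusable intermediate (e.g. empty matrix)."""


class MissingSeedError(InvalidInputError):
    """The seed lncRNA is absent from the expression matrix or index."""


class DegenerateSeedError(InvalidInputError):
    """The seed lncRNA has zero variance; correlations are undefined."""


class EmptyIndexError(InvalidInputError):
    """An interaction table contains no miRNA-involving rows."""


class ZeroVarianceError(InvalidInputError):
    """A vector has zero variance where positive variance is required."""
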