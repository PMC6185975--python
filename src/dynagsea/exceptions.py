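"""Exception hierarchy for dynagsea.

All errors raised by the package derive from :class:`DynagseaError` so callers
can distinguish data/contract problems from programming errors.
"""


class DynagseaError(Exception):
    """Base class for all package errors."""


class FormatError(DynagseaError, ValueError):
    """A file violates its declared format (bad header, duplicate names, ...)."""


class ParseError(FormatError):
    """A specific line of a file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number at which parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmptyMatrixError(DynagseaError, ValueError):
    """Every gene was removed (or none supplied); nothing left to analyse."""


class ContractError(DynagseaError, ValueError):
    """An operation was called with arguments violating its preconditions."""
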