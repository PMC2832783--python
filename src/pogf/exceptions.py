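"""Exception hierarchy for the pogf package."""


class PogfError(Exception):
    """Base class for all pogf errors."""


class ParseError(PogfError):
    """A malformed row in an input file.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnknownGeneError(PogfError, KeyError):
    """A gene symbol that is not a node of the network."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"gene symbol not in network: {symbol!r}")


class ParameterError(PogfError, ValueError):
    """An invalid parameter value (empty list, bad alpha, infeasible sizes)."""


class EmptyListError(ParameterError):
    """A gene list with no usable entries."""
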