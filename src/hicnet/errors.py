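"""Exception hierarchy shared by all hicnet modules."""


class HicnetError(Exception):
    """Base class for all hicnet errors."""


class ValidationError(HicnetError, ValueError):
    """An argument violates a documented precondition."""


class UnknownGeneError(HicnetError, KeyError):
    """A gene symbol is not registered in the store/subgraph."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"unknown gene symbol: {self.symbol!r}"


class UnknownExperimentError(HicnetError, KeyError):
    def __init__(self, name: str, available=()):
        super().__init__(name)
        self.name = name
        self.available = sorted(available)

    def __str__(self) -> str:
        return (
            f"unknown experiment: {self.name!r}; "
            f"available: {', '.join(self.available) or '(none)'}"
        )


class CoordinateConflictError(HicnetError, ValueError):
    """Same gene symbol inserted twice with different genomic intervals."""

    def __init__(self, symbol, existing, new):
        self.symbol, self.existing, self.new = symbol, existing, new
        super().__init__(
            f"gene {symbol!r} already registered at {existing}, "
            f"conflicting insertion at {new}"
        )


class ParseError(HicnetError, ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path, self.line = path, line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)


class ConvergenceError(HicnetError, RuntimeError):
    """Iterative solver failed to converge within max_iter."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter
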