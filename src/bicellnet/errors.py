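"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class BicellnetError(Exception):
    """Base class for all package errors."""


class ConfigError(BicellnetError):
    """Invalid configuration: bad parameter values, infeasible requests."""


class DataError(BicellnetError):
    """Invalid or degenerate input data."""


class ParseError(DataError):
    """Malformed input file; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConvergenceError(BicellnetError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)
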