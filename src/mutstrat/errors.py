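"""Exception hierarchy shared across the pipeline stages."""


class MutstratError(Exception):
    """Base class for all package errors."""


class ParameterError(MutstratError):
    """A configuration or generator parameter is out of its valid range."""


class DataError(MutstratError):
    """Input data are malformed, empty after filtering, or inconsistent."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConvergenceError(MutstratError):
    """An iterative solver hit its iteration cap; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class TrainingError(MutstratError):
    """Neural-network training produced a non-finite loss or empty clusters."""
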