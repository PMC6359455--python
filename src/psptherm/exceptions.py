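"""Exception hierarchy for psptherm."""


class PSPError(Exception):
    """Base class for all psptherm errors."""


class DomainError(PSPError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class ConfigurationError(PSPError):
    """A compound record or run configuration is incomplete or inconsistent."""


class ParseError(PSPError):
    """A tabular input could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ConvergenceError(PSPError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        self.residual = residual
        self.iterations = iterations
        if residual is not None:
            message = f"{message} (last residual {residual:.3e} after {iterations} iterations)"
        super().__init__(message)
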