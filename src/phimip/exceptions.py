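"""Exception types shared across the package."""


class PhimipError(Exception):
    """Base class for package errors."""


class ValidationError(PhimipError, ValueError):
    """Invalid user input (shapes, definiteness, degenerate data)."""


class StationarityError(ValidationError):
    """AR connectivity matrix has spectral radius >= 1: no stationary law."""


class ConvergenceError(PhimipError, RuntimeError):
    """Iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual
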