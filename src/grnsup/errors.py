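"""Exception hierarchy shared across the package."""


class GrnsupError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GrnsupError, ValueError):
    """A parameter violates its documented constraints."""


class ConsistencyError(GrnsupError, RuntimeError):
    """Inputs that should agree (network / profiles / matrix) do not."""


class ConvergenceError(GrnsupError, RuntimeError):
    """Deterministic integration failed to reach a fixed point."""

    def __init__(self, message: str, worst_node: str | None = None, residual: float | None = None):
        super().__init__(message)
        self.worst_node = worst_node
        self.residual = residual


class MetricUndefinedError(GrnsupError, ValueError):
    """A ranking metric is undefined for the given label composition."""
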