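"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration block violates one of its invariants."""


class SolverError(RuntimeError):
    """A steady-state solver failed to converge or the system is singular."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StateError(RuntimeError):
    """A simulation state does not admit the requested operation."""
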