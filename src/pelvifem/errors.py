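"""Exception hierarchy for pelvifem."""


class PelvifemError(Exception):
    """Base class for all package errors."""


class ParameterError(PelvifemError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class GeometryError(PelvifemError):
    """A geometry cannot be built or violates an anatomical invariant."""


class MeshError(PelvifemError):
    """Meshing failed (degenerate surface, zero-area element, ...)."""


class StateError(PelvifemError):
    """A mechanical state is inadmissible (non-positive stretch, ...)."""


class ModelError(PelvifemError):
    """An FE model is inconsistent (missing node set, bad tie, ...)."""


class ConstraintConflictError(ModelError):
    """A tie constraint links degrees of freedom that cannot be reconciled."""


class CalibrationError(PelvifemError):
    """Load calibration failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class ConfigError(PelvifemError, ValueError):
    """Study configuration is invalid; lists every offending path."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


class ReportError(PelvifemError):
    """A descent report could not be assembled."""
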