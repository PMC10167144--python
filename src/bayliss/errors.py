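"""Exception hierarchy for the bayliss package."""


class BaylissError(Exception):
    """Base class for all package errors."""


class InvalidDeformationError(BaylissError):
    """Raised when a deformation state is kinematically inadmissible
    (non-SPD right Cauchy-Green tensor, non-positive Jacobian, ...)."""


class ParameterError(BaylissError):
    """Raised for parameter values outside their admissible range."""


class IntegrationError(BaylissError):
    """Raised when a local Newton iteration fails to converge.

    Carries the final residual norm so callers can decide on
    time-step halving.
    """

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class SolverError(BaylissError):
    """Raised when the ring equilibrium solver fails to converge."""


class ConfigError(BaylissError):
    """Raised for schema violations in run configurations.

    ``fields`` lists every offending field.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class FitError(BaylissError):
    """Raised when a parameter fit cannot be completed."""
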