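"""Exception types shared across the package."""


class MemriError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MemriError, ValueError):
    """An input violates a documented precondition."""


class FitDegenerateError(MemriError):
    """The data carry no usable structure for the requested fit
    (e.g. a constant or non-decaying echo series)."""


class FitConvergenceError(MemriError):
    """The nonlinear optimizer failed to converge from every start."""


class IntegrationError(MemriError):
    """A numerical ODE integration did not complete successfully."""


class PhysicalValidityError(MemriError):
    """A derived biophysical parameter fell outside its physical range.

    Carries the raw offending values so callers can inspect them.
    """

    def __init__(self, message: str, **values: float):
        super().__init__(message)
        self.values = values


class DesignDeficientError(MemriError):
    """The Fisher information matrix is singular: the sampling schedule
    cannot identify all model parameters.  Carries the unidentifiable
    direction (eigenvector of the near-null eigenvalue)."""

    def __init__(self, message: str, direction=None):
        super().__init__(message)
        self.direction = direction


class IdentifiabilityError(DomainError):
    """Too few design points for the number of model parameters."""


class ConfigError(MemriError, ValueError):
    """A configuration document failed schema validation."""


class ParseError(MemriError, ValueError):
    """A signal table could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
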