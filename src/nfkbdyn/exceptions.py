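"""Exception hierarchy."""


class NfkbdynError(Exception):
    """Base class for package errors."""


class ConfigurationError(NfkbdynError):
    """Invalid genotype token, missing parameter, or malformed experiment config."""


class SpecificationError(NfkbdynError):
    """An input-profile or design specification violates its constraints."""


class ValidationError(NfkbdynError):
    """A parameter set or data structure violates its invariants."""


class SimulationError(NfkbdynError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class ConvergenceError(NfkbdynError):
    """Steady-state search did not converge; carries the residual norm."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class AnalysisError(NfkbdynError):
    """A sensitivity or experiment run could not produce a valid result."""
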