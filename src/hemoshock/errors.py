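"""Exception hierarchy for the hemoshock package."""


class HemoshockError(Exception):
    """Base class for all package errors."""


class ParameterError(HemoshockError):
    """A model parameter value or combination violates its physical constraints."""


class ConfigurationError(HemoshockError):
    """A run configuration (file or derived quantity) is invalid or unphysical."""


class SimulationError(HemoshockError):
    """The integrator produced a non-finite or unphysical state.

    Carries the offending time and state vector so the failure can be
    diagnosed without rerunning.
    """

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class ObservationError(HemoshockError):
    """An observation table is malformed or inconsistent with its contract."""
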