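"""Exception types shared across the package."""


class AstrocaError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AstrocaError):
    """A geometric quantity is non-positive or violates a model constraint."""


class InvalidTopologyError(AstrocaError):
    """A morphology specification does not describe a valid connected graph."""


class MissingEdgeError(AstrocaError):
    """A coupling coefficient was requested for a non-adjacent pair."""


class IntegrationError(AstrocaError):
    """The integrator produced a non-finite state.

    Carries the offending compartment label and simulation time.
    """

    def __init__(self, compartment: str, time: float):
        self.compartment = compartment
        self.time = time
        super().__init__(
            f"non-finite state in compartment {compartment!r} at t={time:.6g} s"
        )


class InvalidStepError(AstrocaError):
    """A non-positive time step was supplied."""


class ConfigError(AstrocaError):
    """A run configuration file failed validation."""
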