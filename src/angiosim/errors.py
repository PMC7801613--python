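"""Exception types shared across the simulator."""


class AngiosimError(Exception):
    """Base class for all angiosim errors."""


class StabilityError(AngiosimError):
    """Explicit time step violates the diffusion stability bound."""


class ConfigError(AngiosimError):
    """A simulation configuration field is invalid; message names the field."""


class InvariantViolation(AngiosimError):
    """An internal cross-container consistency check failed."""


class DegenerateInput(AngiosimError):
    """Statistical input carries no usable variance."""
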