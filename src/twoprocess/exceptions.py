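"""Exception hierarchy shared across the package."""


class TwoProcessError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TwoProcessError, ValueError):
    """A parameter set violates a structural constraint."""


class ConfigurationError(TwoProcessError, ValueError):
    """Bad user-supplied configuration (files, flags, waveform tags)."""


class InvalidStateError(TwoProcessError, ValueError):
    """A dynamical state is on the wrong side of an asymptote."""


class PerpetualWakeError(ParameterError):
    """The upper threshold sits at or above the wake asymptote: pressure
    can never reach it and the wake episode would last forever."""


class PerpetualSleepError(ParameterError):
    """The lower threshold sits at or below the sleep asymptote: pressure
    can never fall to it and the sleep episode would last forever."""


class NonTerminatingError(TwoProcessError, RuntimeError):
    """A requested trajectory segment provably never hits its threshold."""
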