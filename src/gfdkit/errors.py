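"""Exception types shared across gfdkit modules."""


class GfdError(Exception):
    """Base class for all gfdkit errors."""


class InvalidParameterError(GfdError, ValueError):
    """A model parameter violates its physical constraint (e.g. tau <= 0)."""


class ConfigurationError(GfdError, ValueError):
    """A simulation/pipeline configuration is inconsistent or unknown."""


class StabilityError(GfdError, ValueError):
    """An explicit integrator was asked to run outside its stability region."""


class InsufficientDataError(GfdError, ValueError):
    """An analysis routine received fewer samples than it needs."""


class UndefinedCapacitanceError(GfdError, ValueError):
    """Series capacitance is undefined for a purely real impedance."""


class FitFailure(GfdError, RuntimeError):
    """A least-squares fit did not converge (returned, not raised, by fitters)."""


class RecordingParseError(GfdError, ValueError):
    """A CSV file does not conform to the expected dialect."""
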