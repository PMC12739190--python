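"""Exception hierarchy for the ddrs package."""


class DDRSError(Exception):
    """Base class for all ddrs errors."""


class ConfigurationError(DDRSError, ValueError):
    """A configuration object violates one of its invariants."""


class ValidationError(DDRSError, ValueError):
    """An input value lies outside its documented domain."""


class InsufficientDataError(DDRSError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(DDRSError, ValueError):
    """A statistic is undefined on this input (zero variance, zero mean...)."""


class CalibrationError(DDRSError, RuntimeError):
    """Generator calibration could not meet its target tolerances."""


class InfeasiblePerturbationError(DDRSError, ValueError):
    """A weight perturbation would push a weight to 1 or beyond."""
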