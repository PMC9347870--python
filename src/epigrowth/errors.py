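"""Exception types shared across the package."""


class EpigrowthError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EpigrowthError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateSupportError(EpigrowthError, ValueError):
    """A discretized distribution would have fewer than two support days."""


class UnsupportedOperationError(EpigrowthError, TypeError):
    """The operation needs structure (e.g. gamma parameters) the object lacks."""


class InvalidProfileError(EpigrowthError, ValueError):
    """A reproduction-number profile is not strictly positive and finite."""


class UndefinedConvolutionError(EpigrowthError, ValueError):
    """Total infectiousness queried at a day with no past incidence."""


class ImpossibleObservationError(EpigrowthError, ValueError):
    """Cases observed on a day with zero total infectiousness."""


class InvalidFilterError(EpigrowthError, ValueError):
    """Savitzky-Golay filter parameters violate their constraints."""


class InvalidInputError(EpigrowthError, ValueError):
    """An input series is too short or otherwise malformed."""


class ConvergenceError(EpigrowthError, RuntimeError):
    """A root finder failed to bracket or converge."""
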