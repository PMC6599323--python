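"""Exception hierarchy shared across the package."""


class FermkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FermkinError, ValueError):
    """A kinetic parameter violates its physical constraints."""


class DomainError(FermkinError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(FermkinError, ValueError):
    """A configuration object (noise spec, fit config) is inconsistent."""


class UnderdeterminedError(FermkinError, ValueError):
    """Fewer informative observations than free parameters."""


class DegenerateDataError(FermkinError, ValueError):
    """Data carry no information about the requested parameters."""


class MissingResponseError(FermkinError, ValueError):
    """A required observable column is absent from the time course."""


class DegenerateStatisticError(FermkinError, ValueError):
    """A goodness-of-fit statistic is undefined (e.g. zero total variance)."""


class UndefinedRatioError(FermkinError, ZeroDivisionError):
    """A ratio against a zero denominator was requested."""


class ValidationError(FermkinError, ValueError):
    """Inputs to a comparison do not match (analyte, unit, length...)."""


class TimeCourseParseError(FermkinError, ValueError):
    """A time-course file could not be parsed; message names the offending row."""


class NegativeConcentrationWarning(UserWarning):
    """The model predicts a negative concentration (mathematically allowed)."""
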