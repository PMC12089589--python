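"""Exception hierarchy shared across the package."""


class PolymrError(Exception):
    """Base class for all package errors."""


class ColumnMappingError(PolymrError):
    """A mandatory column is missing from an input table."""


class EmptySetError(PolymrError):
    """An operation produced or received an empty variant set."""


class HarmonizationError(PolymrError):
    """No usable shared variants between exposure and outcome."""


class InsufficientInstrumentsError(PolymrError):
    """Too few instruments for the requested estimator."""


class DegenerateDesignError(PolymrError):
    """The regression design is degenerate (e.g. all exposure betas zero)."""


class NoInstrumentsError(PolymrError):
    """An instrument set with zero members was passed to mr_analyze."""


class UndefinedRatioError(PolymrError):
    """Wald ratio with a zero exposure beta."""


class AssociationError(PolymrError):
    """Logistic association could not be fitted (separation, constants...)."""


class AnnotationError(PolymrError):
    """Gene annotation file missing or incomplete."""
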