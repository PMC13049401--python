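"""Exception hierarchy for spineharm.

Everything raised deliberately by the package derives from :class:`SpineHarmError`,
so callers can catch one type at tool boundaries.
"""


class SpineHarmError(Exception):
    """Base class for all spineharm errors."""


class UnsupportedFormatError(SpineHarmError):
    """File exists but is not a format/layout the toolkit accepts (e.g. color image)."""


class SchemaError(SpineHarmError):
    """A landmark file violates the 18 vertebrae x 4 corners schema."""


class ValidationError(SpineHarmError):
    """A value violates a documented type invariant."""


class DegenerateInputError(SpineHarmError):
    """An operation received an input it cannot meaningfully process (e.g. empty image)."""


class IncompatibilityError(SpineHarmError):
    """Two objects that must agree on a parameter (n_levels, length, ...) do not."""


class DegenerateEndplateError(SpineHarmError):
    """Left and right corners of an endplate coincide; its slope is undefined."""


class OrderingError(SpineHarmError):
    """Vertebra pair given in the wrong cranio-caudal order."""


class InsufficientDataError(SpineHarmError):
    """Too few samples for the requested statistic."""


class DegenerateRegressionError(SpineHarmError):
    """Regression requested on a predictor with zero variance."""


class ZeroVarianceError(SpineHarmError):
    """Paired test on differences that are all identical; p is undefined."""


class GenerationError(SpineHarmError):
    """A phantom specification cannot be rendered (e.g. overlapping vertebrae)."""


class PlanValidationError(SpineHarmError):
    """An augmentation plan violates its invariants (empty pool, m < 1, ...)."""
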