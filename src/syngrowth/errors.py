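"""Exception hierarchy shared across the package."""


class SyngrowthError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SyngrowthError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(SyngrowthError):
    """Input data violate a structural invariant (negative volume,
    duplicate animal-day, animal in two arms, ...)."""


class InsufficientDataError(SyngrowthError):
    """Too few measurements or animals for the requested estimate."""


class DegenerateInputError(SyngrowthError):
    """A normalizer is zero or a test statistic is undefined
    (vehicle mean rate 0, all four group SEs 0, no events)."""
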