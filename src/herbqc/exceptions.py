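"""Exception hierarchy shared across the pipeline stages."""


class HerbQCError(Exception):
    """Base class for all herbqc errors."""


class ParameterError(HerbQCError, ValueError):
    """A user-supplied parameter is out of its documented range."""


class DataError(HerbQCError, ValueError):
    """Input data violate a structural precondition (empty table, etc.)."""


class DegenerateColumnError(DataError):
    """A matrix column has zero variance and cannot be autoscaled."""


class UndefinedSimilarityError(DataError):
    """Cosine similarity is undefined for a zero-norm profile."""


class FormulaParseError(HerbQCError, ValueError):
    """A molecular formula string does not match the element-count grammar."""


class DomainError(HerbQCError, ValueError):
    """A chemically impossible operation, e.g. a neutral loss leaving
    negative element counts."""


class FitError(HerbQCError, RuntimeError):
    """The regression design matrix is rank deficient."""
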