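"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`GenemetaError`,
so callers can catch one type at the pipeline boundary.
"""


class GenemetaError(Exception):
    """Base class for all errors raised by genemeta."""


class SchemaError(GenemetaError):
    """A study table is missing a required column or has a malformed header."""


class ValidationError(GenemetaError):
    """A study table cell fails validation (bad count, duplicate id, ...)."""


class EmptyGroupError(GenemetaError):
    """A genotype group with zero subjects entered a computation."""


class DegenerateContrastError(GenemetaError):
    """A genetic-model restriction left an empty margin (a+b = 0 or c+d = 0)."""


class DegenerateHWEError(GenemetaError):
    """Hardy-Weinberg test requested on a monomorphic group (p = 0 or 1)."""


class PoolingError(GenemetaError):
    """Pooling received inconsistent or degenerate inputs."""


class InsufficientStudiesError(GenemetaError):
    """Fewer studies than the statistic requires (Egger k >= 3, Begg k >= 2)."""


class NumericalDegeneracyError(GenemetaError):
    """A variance term collapsed to zero or below within tolerance."""


class ConfigurationError(GenemetaError):
    """An option is outside its admissible range."""
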