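"""Exception hierarchy.

Every error raised by this package derives from :class:`HypermorbError`,
so callers can catch one type at a pipeline boundary.
"""


class HypermorbError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HypermorbError):
    """An invalid configuration value (bad probability, empty disease list, ...)."""


class SchemaError(HypermorbError):
    """A file does not conform to the documented cohort CSV schema."""


class ValidationError(HypermorbError):
    """Well-formed data violating a domain invariant (cal_extent > 1, duplicate id, ...)."""


class MatchingError(HypermorbError):
    """Matched-cohort construction cannot proceed (e.g. an empty quartile)."""


class UndefinedWeightError(HypermorbError):
    """An overlap weight is requested for a disease set containing a zero-case disease."""


class DegenerateGraphError(HypermorbError):
    """Eigenvector centrality requested for an all-zero adjacency matrix."""
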