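"""Exception types shared across the pipeline."""


class OwlRSFError(Exception):
    """Base class for package errors."""


class ConfigurationError(OwlRSFError):
    """Invalid generator or model configuration."""


class GeometryError(OwlRSFError):
    """Degenerate or out-of-bounds geometry."""


class OrderingError(OwlRSFError):
    """Input rows violate a required sort order."""


class SchemaError(OwlRSFError):
    """A required column is missing or has the wrong type."""


class RankError(OwlRSFError):
    """Rank-deficient design matrix.

    ``aliased`` names the columns implicated in the deficiency.
    """

    def __init__(self, message: str, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class MissingIndexError(OwlRSFError):
    """An activity index was requested for a stratum never seen in training."""
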