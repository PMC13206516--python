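"""Exception hierarchy for the popscore pipeline.

Every error raised deliberately by this package derives from
:class:`PopscoreError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class PopscoreError(Exception):
    """Base class for all popscore errors."""


class SchemaError(PopscoreError):
    """An input table does not conform to the expected schema."""


class ReferentialError(PopscoreError):
    """A row references a neonate id that does not exist."""


class MissingOutcomeError(PopscoreError):
    """No CRP sample inside the grouping window; the neonate cannot be grouped."""


class InstabilityError(PopscoreError):
    """No sufficiently quiet signal window was found.

    Carries ``min_sd``, the smallest rolling standard deviation achieved,
    so callers can see how far the trace was from qualifying.
    """

    def __init__(self, message: str, min_sd: float | None = None):
        super().__init__(message)
        self.min_sd = min_sd


class DomainError(PopscoreError):
    """An input value lies outside the mathematical domain of an operation."""


class ConfigError(PopscoreError):
    """A configuration object violates its invariants."""
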