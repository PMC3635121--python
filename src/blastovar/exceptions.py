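"""Exception hierarchy for the blastovar pipeline.

All package-specific errors derive from :class:`BlastovarError` so callers can
catch pipeline failures without masking programming errors.
"""


class BlastovarError(Exception):
    """Base class for all blastovar errors."""


class InvalidArgumentError(BlastovarError, ValueError):
    """An argument violates a documented precondition."""


class MissingChannelError(BlastovarError, KeyError):
    """A requested gene channel is not present in the record."""


class EmptyProfileError(BlastovarError):
    """An operation produced or received a profile with no samples."""


class DegenerateFitError(BlastovarError):
    """Too few points (or degenerate geometry) for a requested fit."""


class DegenerateScalingError(BlastovarError):
    """Reference scaling is undefined (target high percentile is zero)."""


class InsufficientPeaksError(BlastovarError):
    """Fewer peaks than required for a range/extent computation."""


class UnclassifiableError(BlastovarError):
    """A stripe-pattern class cannot be assigned (reference stripe absent)."""


class CohortFormatError(BlastovarError):
    """A cohort table violates the tab-delimited dialect."""


class MissingGenotypeError(BlastovarError):
    """A configured comparison references a genotype with no data."""
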