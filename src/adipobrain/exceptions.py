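"""Exception hierarchy for the adipobrain pipeline."""


class AdipobrainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdipobrainError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(AdipobrainError):
    """A value outside the mathematical domain of an operation."""


class InputError(AdipobrainError):
    """Malformed input data (length mismatch, non-finite values, ...)."""


class MissingDataError(AdipobrainError):
    """A required measurement is absent."""


class CollinearityError(AdipobrainError):
    """The covariate design is rank deficient."""


class SupportError(AdipobrainError):
    """Insufficient data support (age coverage, group size) for a fit."""


class DegenerateTrajectoryError(AdipobrainError):
    """A fitted trajectory is flat or otherwise uninvertible."""


class PipelineError(AdipobrainError):
    """A pipeline-level failure (empty retained cohort, failed stage)."""


class SummaryError(AdipobrainError):
    """A summary was requested on a curve with no valid evaluation ages."""
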