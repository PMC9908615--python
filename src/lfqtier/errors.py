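"""Exception hierarchy shared across the pipeline stages."""


class LfqTierError(Exception):
    """Base class for all package errors."""


class FormatError(LfqTierError):
    """Malformed input file (missing header, no intensity columns, ...)."""


class ValidationError(LfqTierError):
    """Inputs violate a documented precondition or invariant."""


class DegeneracyError(ValidationError):
    """A statistic is undefined because the data have no spread.

    Raised by the Significance A stage when the upper percentile anchor
    coincides with the median: the ratio distribution has no upper spread
    and no outlier can be standardised against it.
    """
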