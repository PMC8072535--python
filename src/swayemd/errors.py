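"""Exception hierarchy for the sway-analysis pipeline.

Every stage raises a subclass of :class:`SwayEMDError` so callers (and the
CLI) can catch pipeline failures without masking programming errors.
"""


class SwayEMDError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SwayEMDError):
    """A trial or metadata file cannot be parsed into the expected shape."""


class DegenerateLoadError(SwayEMDError):
    """Vertical force contains a zero sample; COP is undefined there."""


class LengthError(SwayEMDError):
    """A series is too short for the requested operation."""


class NotDecomposableError(SwayEMDError):
    """A signal lacks the extrema needed to build spline envelopes."""


class UndefinedFeatureError(SwayEMDError):
    """A feature value is mathematically undefined for this input."""


class IntegrityError(SwayEMDError):
    """Duplicate or inconsistent records in a cohort table."""


class LabelError(SwayEMDError):
    """A subject carries an unknown group label."""


class ValidationError(SwayEMDError):
    """A configuration or spec object violates its invariants."""
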