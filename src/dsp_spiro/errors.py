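"""Exception hierarchy used across the pipeline.

Readers reject malformed input rather than coercing it; every stage raises
one of these so callers can distinguish bad parameters from bad data.
"""


class DspSpiroError(Exception):
    """Base class for all package errors."""


class ParameterError(DspSpiroError, ValueError):
    """A configuration or argument value is invalid."""


class FormatError(DspSpiroError, ValueError):
    """A file does not conform to its expected on-disk format."""


class DataError(DspSpiroError, ValueError):
    """Well-formed input whose content violates a contract (e.g. non-monotone time)."""


class AlignmentError(DataError):
    """Audio and IMU streams do not overlap in session time."""
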