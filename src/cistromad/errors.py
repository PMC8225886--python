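"""Exception hierarchy shared across the pipeline.

Each class maps to a process exit code used by the CLI:
configuration errors exit 2, data validation errors exit 3,
stage computation errors exit 4.
"""


class CistromadError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ConfigurationError(CistromadError):
    """A parameter or config file is invalid before any data is touched."""

    exit_code = 2


class ValidationError(CistromadError):
    """Input data violates a documented invariant."""

    exit_code = 3


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class SchemaError(ValidationError):
    """A table is missing a required column or condition."""


class AlignmentError(ValidationError):
    """Two parallel inputs that must be one-to-one are not."""


class UndefinedRatioError(CistromadError):
    """A log ratio is undefined (zero counts with no pseudocount)."""


class DegenerateSpreadError(CistromadError):
    """MAD of the ratio distribution is zero; thresholds are meaningless."""


class EnumerationLimitError(CistromadError):
    """Variable-modification enumeration exceeded the configured cap."""


class SequenceError(ValidationError):
    """A protein sequence contains a non-amino-acid letter."""
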