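"""Exception hierarchy shared across the package.

Exit-code mapping in the CLI distinguishes configuration, data, and
estimation failures, so the hierarchy keeps those three branches separate.
"""


class ClaimsCohortError(Exception):
    """Base class for all package errors."""


class ConfigError(ClaimsCohortError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(ClaimsCohortError):
    """Input table does not conform to the expected schema."""


class DataError(ClaimsCohortError):
    """Row-level input problem (unparseable date, bad enum value, ...)."""


class InvalidCodeError(DataError):
    """Empty or blank diagnosis/prescription code."""


class EstimationError(ClaimsCohortError):
    """Statistical estimation cannot proceed (single cohort, zero exposure...)."""
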