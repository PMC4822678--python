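"""Exception hierarchy shared across the package."""


class Hnf1bError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(Hnf1bError):
    """A delimited-text file does not conform to the cohort schema."""


class CohortValidationError(Hnf1bError):
    """A record or cohort violates a structural invariant."""


class DegenerateTableError(Hnf1bError):
    """A 2x2 table (or stratum set) carries no usable information."""
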