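class TwinvolError(Exception):
    """Base class for all package errors."""


class CohortError(TwinvolError):
    """Base class for cohort construction/validation errors."""


class SchemaError(CohortError):
    """A required column is absent or malformed."""


class IntegrityError(CohortError):
    """Structural inconsistency (duplicate IDs, conflicting roles)."""


class ValidationError(CohortError):
    """Values outside the permitted vocabulary or range."""


class FitError(TwinvolError):
    """Model fitting could not be carried out as requested."""
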