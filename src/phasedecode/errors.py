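"""Exception types shared across the package."""


class PhaseDecodeError(Exception):
    """Base class for all phasedecode errors."""


class ValidationError(PhaseDecodeError, ValueError):
    """An argument or configuration violates a documented precondition."""


class SchemaError(ValidationError):
    """A serialized container is malformed or missing a required field."""


class BoundsError(ValidationError):
    """A requested window, segment or index falls outside the data."""


class UndefinedPhaseError(PhaseDecodeError):
    """An operation received a phase flagged as undefined (NaN)."""


class InsufficientNullError(ValidationError):
    """Too few surrogate samples to form a null distribution."""
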