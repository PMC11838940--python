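"""Exception hierarchy shared across the package."""


class TecoError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TecoError):
    """An input table does not match the declared column schema."""


class CohortValidationError(TecoError):
    """Row-level invariant violations in strict validation mode."""


class EmptyCohortError(TecoError):
    """An operation requiring a non-empty cohort received an empty one."""


class ConfigurationError(TecoError):
    """An invalid model/training/evaluation configuration."""


class EncodingError(TecoError):
    """A categorical level not present in the feature schema."""


class DegenerateLabelError(TecoError):
    """Training or evaluation received a single-class label vector."""


class UndefinedAUCError(DegenerateLabelError):
    """AUC is undefined because only one outcome class is present."""


class CheckpointError(TecoError):
    """A checkpoint is incompatible with the requested schema/config."""
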