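"""Exception taxonomy shared across the package."""


class CariesDtaError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(CariesDtaError):
    """A file or frame does not match the expected schema."""


class DataValidationError(CariesDtaError):
    """A record violates a domain invariant (counts, margins, ranges)."""


class DuplicateKeyError(CariesDtaError):
    """Two arms share the (study_id, technology, dataset_label, threshold) key."""


class UnknownTechnologyError(CariesDtaError):
    """A technology name is not present in the active registry."""


class EligibilityError(CariesDtaError):
    """A table does not meet a model's design requirements."""


class ModelSpecError(CariesDtaError):
    """Parameters are inconsistent with the requested model variant."""


class ConfigError(CariesDtaError):
    """A run or simulation configuration is invalid."""
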