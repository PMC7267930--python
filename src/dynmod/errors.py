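"""Exception hierarchy shared across the pipeline stages."""


class DynmodError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DynmodError):
    """Invalid simulation or pipeline configuration."""


class DataValidationError(DynmodError):
    """A tabular artifact failed validation (ragged rows, NaN, bad labels)."""


class AlignmentError(DynmodError):
    """Cohort components (series, labels, phenotype) do not line up."""


class InsufficientDataError(DynmodError):
    """Too few time points / windows / subjects for the requested operation."""


class DegenerateInputError(DynmodError):
    """Input is formally valid but the quantity is undefined on it."""
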