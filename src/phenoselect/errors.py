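"""Exception hierarchy shared by all stages of the pipeline."""


class PhenoselectError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PhenoselectError):
    """A configuration value violates a stated constraint."""


class SchemaError(PhenoselectError):
    """A table or file does not match the expected schema."""


class DataError(PhenoselectError):
    """Input data are unusable (non-finite values, empty result, ...)."""


class LabelError(DataError):
    """Class labels are unusable (single class, non-binary, ...)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(DataError):
    """Input is degenerate (e.g. zero variance) for the requested statistic."""


class DimensionalityError(DataError):
    """More traits than samples where an exact computation needs p < n."""
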