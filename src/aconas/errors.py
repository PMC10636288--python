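"""Exception hierarchy shared across the package."""


class AconasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AconasError):
    """Structurally invalid input file (duplicate ids, bad shape, ...)."""


class ParseError(AconasError):
    """A cell could not be parsed; message names the offending location."""


class ConfigError(AconasError):
    """Invalid configuration or hyperparameter value."""


class EncodingError(AconasError):
    """Individual cannot be encoded under the given pool."""


class DecodingError(AconasError):
    """Vector is not a valid encoding under the given pool."""


class AlignmentError(AconasError):
    """Prediction input genes do not match the trained model."""


class TrainingDivergedError(AconasError):
    """Non-finite loss encountered during network training."""
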