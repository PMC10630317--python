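"""Package-wide exception types."""


class FibranetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FibranetError, ValueError):
    """Invalid generator / analysis configuration."""


class FormatError(FibranetError, ValueError):
    """Input file does not match the expected format."""


class InsufficientDataError(FibranetError, ValueError):
    """Not enough samples to run the requested estimator."""


class FitRejectedError(FibranetError, RuntimeError):
    """A model fit failed its quality gate."""
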