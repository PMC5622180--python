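"""Exception hierarchy.

Errors are split into configuration problems (bad parameters, missing
paths — CLI exit code 2) and data problems (malformed files, failed
waveform feature detection, degenerate fits — CLI exit code 3).
"""


class ErgthermError(Exception):
    """Base class for all package errors."""


class ConfigError(ErgthermError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class ParameterError(ConfigError):
    """A numeric parameter is out of its valid range."""


class DataError(ErgthermError):
    """Problem with input data (CLI exit code 3)."""


class FormatError(DataError):
    """Malformed session/trace/feature file."""


class PreconditionError(DataError):
    """An operation's precondition on its input data is violated."""


class DetectionError(DataError):
    """A waveform feature could not be located on a trace."""


class FittingError(DataError):
    """Least-squares fit failed (for example a rank-deficient design)."""


class PredictionError(DataError):
    """Prediction impossible (for example missing model features)."""
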