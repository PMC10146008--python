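"""Exception hierarchy shared across the pipeline stages."""


class PPGBPError(Exception):
    """Base class for all package errors."""


class ParseError(PPGBPError):
    """A text input could not be parsed (message names the offending line)."""


class SamplingError(PPGBPError):
    """Sampling rate inconsistent with the data, or below the supported floor."""


class InsufficientDataError(PPGBPError):
    """Too few beats / intervals / subjects for the requested computation."""


class NoBeatsError(InsufficientDataError):
    """No pulses could be detected in the signal."""


class SchemaError(PPGBPError):
    """Feature table or prediction schema mismatch."""


class DataError(PPGBPError):
    """Invalid training/evaluation data (e.g. missing feature values)."""


class DomainError(PPGBPError, ValueError):
    """A value outside its mathematical or physiological domain."""


class ConfigError(PPGBPError):
    """Invalid configuration (ranges, rates, parameter combinations)."""


class WidthUndefinedError(PPGBPError):
    """A fractional-width level is never crossed on one side of the peak."""


class StateError(PPGBPError):
    """Operation requested on an object in the wrong state (e.g. untrained net)."""


class LeakageError(PPGBPError):
    """Evaluation data found inside a training split."""


class AlignmentError(PPGBPError):
    """Subject sets of two result series do not match."""
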