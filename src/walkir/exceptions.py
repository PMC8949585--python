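"""Exception hierarchy for walkir."""


class WalkIRError(Exception):
    """Base class for all walkir errors."""


class InvalidBaselineError(WalkIRError):
    """Baseline record is unusable (e.g. zero habitual walking speed)."""


class SpanError(WalkIRError):
    """A date or day index falls outside the requested span/horizon."""


class InsufficientDataError(WalkIRError):
    """Too few observations to perform the requested estimation."""


class UnidentifiableError(WalkIRError):
    """Model parameters cannot be identified from the data (e.g. zero load)."""


class UndefinedDecayError(WalkIRError):
    """Detraining decay is undefined: no positive training-induced gain."""


class DegenerateDataError(WalkIRError):
    """Input data are degenerate for the requested statistic."""


class UndefinedStatisticError(WalkIRError):
    """The statistic is undefined for these data (e.g. zero total variance)."""


class DataFormatError(WalkIRError):
    """A data file could not be parsed; the message names the offending row."""


class ConfigError(WalkIRError):
    """Invalid run configuration."""
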