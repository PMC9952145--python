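"""Exception hierarchy shared across the pipeline."""


class PPGScreenError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(PPGScreenError):
    """Sampling rate too coarse to resolve the requested pulse morphology."""


class ConfigurationError(PPGScreenError):
    """Invalid generator or pipeline configuration."""


class FilterDesignError(PPGScreenError):
    """Band-pass design failed (e.g. unstable at the requested order)."""


class RecordTooShortError(PPGScreenError):
    """Recording shorter than the filter's padding requirement."""


class NoBeatsError(PPGScreenError):
    """No pulse beats could be segmented from the signal."""


class MalformedBeatError(PPGScreenError):
    """A beat violates the structural assumptions of a fiducial or feature."""


class SubjectExcludedError(PPGScreenError):
    """Too few valid beats to aggregate a subject."""


class BalanceError(PPGScreenError):
    """Class rebalancing is impossible (fewer than two classes)."""


class FoldError(PPGScreenError):
    """A class has too few members for the requested number of CV folds."""


class SchemaError(PPGScreenError):
    """Feature-matrix schema does not match what a model or stage expects."""
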