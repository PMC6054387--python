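"""Exception hierarchy for metgblup."""


class MetGblupError(Exception):
    """Base class for all metgblup errors."""


class StructureError(MetGblupError):
    """Invalid or non-positive-definite covariance structure."""


class ModelError(MetGblupError):
    """Inconsistent model inputs (dimension mismatch, non-PSD G0, ...)."""


class NumericalError(MetGblupError):
    """Singular or numerically unusable linear system."""


class EmptyPanelError(MetGblupError):
    """Marker filtering removed every marker."""


class UndefinedCorrelationError(MetGblupError):
    """Pearson correlation undefined (zero variance in one vector)."""


class ConfigError(MetGblupError):
    """Invalid run configuration."""


class PriorError(MetGblupError):
    """Invalid prior specification for the Bayesian sampler."""
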