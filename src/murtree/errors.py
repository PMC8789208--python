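"""Exception types shared across the package."""


class MurtreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MurtreeError):
    """A delimited-text table violates the documented schema."""


class OutcomeUndefinedError(MurtreeError):
    """PPR/TTHR requested for an edition whose attendance is unresolved."""


class UnresolvableMissingError(MurtreeError):
    """A missing attendance value matches neither imputation rule."""


class ClassificationError(MurtreeError):
    """A predictor class cannot be assigned (e.g. all ages missing)."""


class RoutingError(MurtreeError):
    """An observation cannot be routed through a fitted tree."""


class UndefinedStatisticError(MurtreeError):
    """A statistic (R^2, rel error, slope) is undefined for the input."""


class AdjustmentError(MurtreeError):
    """Temperature adjustment requested but no temperature is available."""


class ConfigError(MurtreeError):
    """Invalid generator or fit configuration."""
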