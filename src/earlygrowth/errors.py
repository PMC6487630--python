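"""Exception types shared across the package."""


class EarlyGrowthError(ValueError):
    """Base class for domain and configuration errors."""


class DomainError(EarlyGrowthError):
    """A measurement or parameter is outside its physiologic/valid domain."""


class ConfigurationError(EarlyGrowthError):
    """An invalid simulation or pipeline configuration."""


class SingularModelError(EarlyGrowthError):
    """A regression design is rank deficient or otherwise degenerate."""


class ChartRangeError(EarlyGrowthError):
    """A query age falls outside a reference chart's supported range."""
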