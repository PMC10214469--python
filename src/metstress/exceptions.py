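"""Exception hierarchy for trial validation and analysis errors."""


class MetstressError(Exception):
    """Base class for all package errors."""


class SchemaError(MetstressError):
    """A mandatory column is missing or the column mapping is invalid."""


class ValidationError(MetstressError):
    """A record violates a dataset invariant (enum, range, uniqueness)."""


class UnbalancedDesignError(MetstressError):
    """The requested analysis requires a balanced design."""


class UndefinedRatioError(MetstressError):
    """A ratio with a zero denominator was requested."""


class NoStressError(MetstressError):
    """The stress environment does not yield below the optimum (SI <= 0)."""


class ConfigError(MetstressError):
    """Invalid simulation or analysis configuration."""
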