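"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a task, tuning, or policy configuration is internally inconsistent."""


class SingularFitError(ValueError):
    """Raised when a model fit is rank deficient (e.g. duplicated neural channels)."""


class InsufficientSegmentsError(ValueError):
    """Raised when a stratum lacks the minimum labeled segments for balanced training."""


class SchemaError(ValueError):
    """Raised on session/model file schema-version mismatch or truncation."""
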