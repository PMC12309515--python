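"""Exception types shared across the package."""


class CTSurveilError(Exception):
    """Base class for package errors."""


class ConfigurationError(CTSurveilError, ValueError):
    """Invalid configuration value (rates, windows, margins, thresholds)."""


class ParseError(CTSurveilError, ValueError):
    """Malformed input that could not be parsed; carries location info."""


class IntegrityError(CTSurveilError, ValueError):
    """Referential-integrity or uniqueness violation in loaded data."""


class SchemaError(CTSurveilError, ValueError):
    """Serialized artifact does not match the library's schema/version."""


class NotFittedError(CTSurveilError, RuntimeError):
    """Operation requires a fitted model."""
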