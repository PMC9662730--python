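"""Exception hierarchy used across the pipeline."""


class SpectrotexError(Exception):
    """Base class for all package errors."""


class ValidationError(SpectrotexError):
    """Input data violates an invariant (NaN samples, missing channels...)."""


class ConfigurationError(SpectrotexError):
    """A configuration value is inconsistent or out of range."""
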