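"""Package-wide exception types."""


class WmlearnError(Exception):
    """Base class for all package errors."""


class ConfigError(WmlearnError):
    """A configuration value is invalid (non-positive SD, bad probability...)."""


class DomainError(WmlearnError):
    """An input is outside the operation's domain (e.g. trial index < 1)."""


class SaturationError(WmlearnError):
    """A predicted probability reached 0 or 1 while the observed outcome
    disagrees, which would make the Bernoulli log likelihood -inf."""


class FitError(WmlearnError):
    """Model fitting failed (optimizer or sampler did not produce a result)."""


class SchemaError(WmlearnError):
    """A data table violates the expected schema."""
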