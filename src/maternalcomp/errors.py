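"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A numeric argument is out of range, non-finite, or otherwise invalid."""


class ConfigError(ValueError):
    """A run configuration is missing fields, has unknown keys, or fails validation."""


class UnderdeterminedError(ValueError):
    """Too few usable time-series transitions to identify the model parameters."""


class UnidentifiableError(ValueError):
    """An environment stratum required by the model was never observed."""
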