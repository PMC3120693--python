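"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A function argument or configuration value is invalid."""


class DataError(RuntimeError):
    """Input data is unreadable, malformed, or inconsistent."""


class ConfigError(ParameterError):
    """A pipeline configuration file is invalid."""
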