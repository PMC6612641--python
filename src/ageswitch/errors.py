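"""Exception types shared across the pipeline."""


class AgeswitchError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(AgeswitchError, ValueError):
    """A generator or stage was configured with inconsistent parameters."""


class InvalidInputError(AgeswitchError, ValueError):
    """Input data violates a documented precondition."""


class WindowTooSmallError(InvalidInputError):
    """An age window holds fewer samples than the scan requires."""


class EmptyTemplateError(InvalidInputError):
    """All probes were filtered out; no summarization template remains."""


class ConfigError(AgeswitchError, ValueError):
    """A run configuration file failed schema validation."""
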