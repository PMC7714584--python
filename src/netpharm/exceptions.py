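"""Exception hierarchy used across the pipeline."""


class NetpharmError(Exception):
    """Base class for all package errors."""


class ConfigError(NetpharmError, ValueError):
    """A configuration value is outside its stated domain.

    The message always names the offending field.
    """


class InputError(NetpharmError, ValueError):
    """An input (file or in-memory argument) violates a precondition."""


class StageError(NetpharmError, RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
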