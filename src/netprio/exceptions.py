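"""Exception hierarchy shared across the package."""


class NetprioError(Exception):
    """Base class for package errors."""


class ConfigurationError(NetprioError, ValueError):
    """Invalid parameter or configuration value."""


class MalformedInputError(NetprioError, ValueError):
    """A file or table violates its format contract."""


class PipelineStageError(NetprioError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
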