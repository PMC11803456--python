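"""Exception hierarchy shared by all pipeline stages."""


class HgaMapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(HgaMapError):
    """Invalid configuration or paradigm parameters."""

    exit_code = 2


class DataError(HgaMapError):
    """Invalid, inconsistent, or degenerate input data."""

    exit_code = 3


class PipelineError(HgaMapError):
    """A stage failed; carries the stage name for context."""

    exit_code = 1

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
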