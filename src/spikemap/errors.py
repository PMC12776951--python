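"""Exception hierarchy."""


class SpikemapError(Exception):
    """Base class for all spikemap errors."""


class FormatError(SpikemapError, ValueError):
    """A file or in-memory object violates a format contract."""


class ConfigError(SpikemapError, ValueError):
    """A pipeline configuration is invalid."""


class StageError(SpikemapError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
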