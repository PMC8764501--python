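"""Exception types shared across the pipeline."""


class ConfigurationError(RuntimeError):
    """A required configuration element (RR entry, PAF row, life-table band,
    site/sex applicability) is missing or inconsistent."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
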