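"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """A configuration or input failed an invariant check."""


class ParseError(ValueError):
    """A CSV/JSON artifact could not be parsed; carries file position."""


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
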