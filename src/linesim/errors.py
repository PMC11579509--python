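"""Exception hierarchy shared by all modules."""


class LinesimError(Exception):
    """Base class for all linesim errors."""


class ValidationError(LinesimError, ValueError):
    """Input data or configuration violates a documented contract."""


class StageError(LinesimError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
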