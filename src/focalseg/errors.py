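"""Exception hierarchy shared across the pipeline stages."""


class FocalsegError(Exception):
    """Base class for all focalseg errors."""


class ValidationError(FocalsegError, ValueError):
    """A configuration or specification field failed validation."""


class FormatError(FocalsegError, ValueError):
    """An input file is unreadable or in an unsupported format."""


class LabelError(FocalsegError, ValueError):
    """A label image violates the binary {0,1} / {0,255} contract."""


class ShapeError(FocalsegError, ValueError):
    """Array dimensions violate an operation's contract."""


class StageError(FocalsegError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
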