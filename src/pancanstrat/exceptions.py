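"""Exception hierarchy shared across the package."""


class PancanstratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PancanstratError, ValueError):
    """A file does not conform to its declared dialect (ragged rows, short GMT lines, ...)."""


class ParseError(FormatError):
    """A cell that should be numeric is not; the message carries row/column context."""


class EmptyCohortError(PancanstratError, ValueError):
    """A filter removed every gene or every primary site."""


class ConstantGeneError(PancanstratError, ValueError):
    """A gene with zero variance was passed to a correlation-based step."""


class ZeroVectorError(PancanstratError, ValueError):
    """A sample expression vector has zero norm, so cosine distance is undefined."""


class PipelineStageError(PancanstratError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` holds the original error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
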