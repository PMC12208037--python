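"""Exception types shared across the pipeline."""


class EdscreenError(Exception):
    """Base class for package errors."""


class ParameterError(EdscreenError, ValueError):
    """Invalid cohort / rule / design parameterization."""


class RecordValidationError(EdscreenError, ValueError):
    """A patient record carries physically impossible values (corrupt input)."""


class CalibrationError(EdscreenError, ValueError):
    """The requested confusion-cell target is unreachable under the generative model."""


class DesignError(EdscreenError, ValueError):
    """Verification-sampling design cannot be realized (e.g. an empty stratum sample)."""


class AlignmentError(EdscreenError, ValueError):
    """Decisions and labels do not refer to the same set of visits."""


class UndefinedMetricError(EdscreenError, ZeroDivisionError):
    """A diagnostic metric's denominator is zero; the message names the metric."""


class PipelineStageError(EdscreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
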