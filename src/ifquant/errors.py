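"""Exception types shared across the pipeline.

Every stage raises a specific subclass of :class:`IFQuantError` so the
orchestrator can attach stage identity and fail fast with a useful message.
"""


class IFQuantError(Exception):
    """Base class for all package errors."""


class DegenerateImageError(IFQuantError):
    """Raised when an image has zero dynamic range (constant intensity)."""


class DegenerateBaselineError(IFQuantError):
    """Raised when the lowest-decile baseline of a channel is zero."""


class SceneOvercrowdedError(IFQuantError):
    """Raised when requested nuclei cannot be placed within the attempt budget."""


class ConfigError(IFQuantError):
    """Raised on invalid run configuration, before any image work starts."""


class StageError(IFQuantError):
    """Wraps an error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
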