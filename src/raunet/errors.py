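"""Exception hierarchy for the segmentation toolkit."""


class RAUNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RAUNetError):
    """A spec/shape/channel configuration is inconsistent."""


class ShapeError(RAUNetError):
    """An input grid has the wrong dimensionality or extent."""


class DegenerateVolumeError(RAUNetError):
    """A volume violates a numeric precondition (e.g. constant intensities)."""


class EmptySegmentationError(RAUNetError):
    """A cascade stage produced no foreground voxels."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"stage '{stage}' produced an empty segmentation")


class TrainingDivergedError(RAUNetError):
    """The training loss became non-finite."""
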