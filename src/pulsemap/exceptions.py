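"""Exception types raised by the pipeline stages."""


class PulsemapError(Exception):
    """Base class for all pipeline errors."""


class ChannelMismatchError(PulsemapError, ValueError):
    """A clip's channel count or labels differ from what the caller declared."""


class ClipTooShortError(PulsemapError, ValueError):
    """A clip has fewer frames than an operation requires (e.g. sub-4 s videos)."""


class NoFaceError(PulsemapError, RuntimeError):
    """The face detector found no face on any sampled frame."""


class DegenerateImageError(PulsemapError, ValueError):
    """An image is constant/unimodal where a threshold or clustering is undefined."""


class SegmentationBackendError(PulsemapError, RuntimeError):
    """The pluggable person-segmentation backend failed."""


class EmptySkinMaskError(PulsemapError, RuntimeError):
    """Skin segmentation produced an empty mask."""


class NonSquareClipError(PulsemapError, ValueError):
    """Dual-resolution reshaping requires a square-cropped clip."""
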