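"""Video clip container and lossless clip I/O.

A :class:`VideoClip` is the uniform in-memory representation used by every
pipeline stage: a ``T x H x W x C`` frame stack with a frame rate and ordered
wavelength-channel labels (e.g. ``("B", "G", "R")`` for a visible-spectrum
camera, ``("NIR",)`` or ``("LWIR",)`` for the infrared cameras).  Pixel values
use 8-bit gray-level semantics (0-255) but may be stored as floats.

Clips are persisted losslessly either as NPZ archives (frames + metadata in
one file) or as multi-page TIFF stacks with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .exceptions import ChannelMismatchError, ClipTooShortError

__all__ = ["VideoClip", "read_clip", "write_clip", "slice_initial"]


@dataclass
class VideoClip:
    """A frame stack with sampling metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W, C)``; a ``(T, H, W)`` array is accepted
        and promoted to a single channel.
    fps
        Frame rate :math:`f_s` in Hz.  The sampling period is
        :math:`T_S = 1/f_s`.
    channel_labels
        One wavelength tag per channel, in storage order.
    source_id
        Free-form provenance string (file name, synthetic recipe, ...).
    """

    frames: np.ndarray
    fps: float
    channel_labels: tuple[str, ...] = ("G",)
    source_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 3:
            frames = frames[..., np.newaxis]
        if frames.ndim != 4:
            raise ValueError(f"frames must be (T, H, W, C); got shape {frames.shape}")
        t, h, w, c = frames.shape
        if min(t, h, w) < 1 or c not in (1, 3):
            raise ValueError(f"invalid clip shape {frames.shape}; C must be 1 or 3")
        self.frames = frames
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != c:
            raise ChannelMismatchError(
                f"{c} channels but labels {self.channel_labels}"
            )
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.fps = float(self.fps)

    # -- shape accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[3]

    @property
    def sampling_period(self) -> float:
        """Sampling period ``T_S = 1 / fps`` in seconds."""
        return 1.0 / self.fps

    def channel_index(self, label: str) -> int:
        """Index of the channel tagged ``label`` (case-insensitive)."""
        labels = [c.upper() for c in self.channel_labels]
        try:
            return labels.index(label.upper())
        except ValueError:
            raise ChannelMismatchError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """The ``(T, H, W)`` frame stack of one wavelength channel."""
        return self.frames[..., self.channel_index(label)]

    def with_frames(self, frames: np.ndarray) -> "VideoClip":
        """Copy of this clip with replaced frame data (metadata preserved)."""
        return replace(self, frames=frames)


def write_clip(clip: VideoClip, path: str | Path) -> Path:
    """Write a clip losslessly.

    ``.npz`` stores frames and metadata in one archive; ``.tif``/``.tiff``
    stores a multi-page stack plus a ``<stem>.json`` sidecar.
    """
    path = Path(path)
    meta = {
        "fps": clip.fps,
        "channel_labels": list(clip.channel_labels),
        "source_id": clip.source_id,
    }
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=clip.frames, meta=json.dumps(meta))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, clip.frames)
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported container {path.suffix!r}; use .npz or .tif")
    return path


def read_clip(
    path: str | Path,
    expected_channels: int | Sequence[str] | None = None,
    fps: float | None = None,
) -> VideoClip:
    """Read a clip written by :func:`write_clip`.

    Parameters
    ----------
    expected_channels
        Either a channel count or a sequence of labels; a mismatch with the
        stored clip raises :class:`ChannelMismatchError`.
    fps
        Override for the stored frame rate (required if the sidecar is
        missing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            frames = archive["frames"]
            meta = json.loads(str(archive["meta"]))
    elif path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        elif fps is not None:
            meta = {"fps": fps, "channel_labels": None, "source_id": str(path)}
        else:
            raise FileNotFoundError(f"metadata sidecar {sidecar} missing and no fps given")
    else:
        raise ValueError(f"unsupported container {path.suffix!r}")

    if frames.ndim == 3:
        frames = frames[..., np.newaxis]
    labels = meta.get("channel_labels") or (
        ("B", "G", "R") if frames.shape[-1] == 3 else ("G",)
    )
    clip = VideoClip(
        frames=frames,
        fps=fps if fps is not None else meta["fps"],
        channel_labels=tuple(labels),
        source_id=meta.get("source_id", str(path)),
    )
    if expected_channels is not None:
        if isinstance(expected_channels, int):
            ok = clip.n_channels == expected_channels
        else:
            ok = tuple(s.upper() for s in expected_channels) == tuple(
                s.upper() for s in clip.channel_labels
            )
        if not ok:
            raise ChannelMismatchError(
                f"expected {expected_channels}, found {clip.channel_labels}"
            )
    return clip


def slice_initial(clip: VideoClip, n_frames: int) -> VideoClip:
    """Keep only the first ``n_frames`` frames (e.g. the initial 4 s).

    Raises :class:`ClipTooShortError` for shorter clips, mirroring the
    exclusion of recordings that do not cover the full analysis window;
    the caller decides whether to skip the clip.
    """
    if clip.n_frames < n_frames:
        raise ClipTooShortError(
            f"clip has {clip.n_frames} frames; {n_frames} required"
        )
    return clip.with_frames(clip.frames[:n_frames])
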