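"""Facial region-of-interest detection and cropping.

Two paths, matching the two camera families:

* reflective (RGB / NIR): a pluggable per-frame face detector is run on
  every ``sample_stride``-th frame and the detected boxes are averaged
  coordinate-wise, yielding one crop box for the whole clip;
* thermal (LWIR): the face is warmer than the background, so a blurred
  average of a few sampled frames is Otsu-thresholded and the mask's
  bounding box is the crop.

The detector backend is any callable ``frame -> list of (x0, y0, w, h)``.
The default is a simple brightness-blob detector (Otsu foreground, largest
connected component), adequate for the synthetic scenes; real deployments
plug in a trained face detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .exceptions import DegenerateImageError, NoFaceError
from .video_io import VideoClip

__all__ = [
    "ROIBox",
    "brightness_blob_detector",
    "detect_face_roi_reflective",
    "detect_face_roi_thermal",
    "crop_clip",
    "square_box",
]

BoxTuple = tuple[int, int, int, int]
Detector = Callable[[np.ndarray], Sequence[BoxTuple]]


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned crop rectangle (0-based top-left corner)."""

    x0: int
    y0: int
    width: int
    height: int

    def clipped(self, frame_h: int, frame_w: int) -> "ROIBox":
        x0 = min(max(self.x0, 0), frame_w - 1)
        y0 = min(max(self.y0, 0), frame_h - 1)
        return ROIBox(
            x0=x0,
            y0=y0,
            width=max(1, min(self.width, frame_w - x0)),
            height=max(1, min(self.height, frame_h - y0)),
        )

    @property
    def area(self) -> int:
        return self.width * self.height


def brightness_blob_detector(frame: np.ndarray) -> list[BoxTuple]:
    """Default detector: bounding box of the largest above-background blob.

    Foreground = pixels well above the border-estimated background level
    (the subject region, whatever its skin tone); the largest connected
    component is reported.  Returns an empty list on constant frames.
    A trained face detector can be plugged in instead.
    """
    from .skin_segmentation import border_background_backend

    gray = frame.mean(axis=-1) if frame.ndim == 3 else np.asarray(frame, dtype=float)
    if np.ptp(gray) == 0:
        return []
    mask = border_background_backend(gray)
    if not mask.any():
        return []
    labels = cc_label(mask)
    best = max(regionprops(labels), key=lambda r: r.area)
    r0, c0, r1, c1 = best.bbox
    return [(c0, r0, c1 - c0, r1 - r0)]


def detect_face_roi_reflective(
    clip: VideoClip,
    sample_stride: int = 10,
    detector: Detector | None = None,
) -> ROIBox:
    """Averaged face box over every ``sample_stride``-th frame.

    On frames with multiple detections the largest box is kept (single
    subject assumed).  Each box coordinate is averaged arithmetically over
    the sampled frames and rounded to the nearest integer.

    Raises :class:`NoFaceError` when no sampled frame yields a detection.
    """
    detector = detector or brightness_blob_detector
    boxes: list[BoxTuple] = []
    for ti in range(0, clip.n_frames, sample_stride):
        found = list(detector(clip.frames[ti]))
        if found:
            boxes.append(max(found, key=lambda b: b[2] * b[3]))
    if not boxes:
        raise NoFaceError("no face detected on any sampled frame")
    mean = np.mean(np.asarray(boxes, dtype=float), axis=0)
    x0, y0, w, h = (int(round(v)) for v in mean)
    return ROIBox(x0=x0, y0=y0, width=w, height=h).clipped(clip.height, clip.width)


def detect_face_roi_thermal(
    clip: VideoClip, n_samples: int = 3
) -> tuple[np.ndarray, ROIBox]:
    """Thermal face mask and bounding box.

    Averages ``n_samples`` uniformly sampled frames (first, middle, last for
    the default 3), min-max normalizes, blurs with a 5x5 averaging kernel
    and Otsu-thresholds the result; the warmer side is the face.

    Raises :class:`DegenerateImageError` for constant images (Otsu undefined).
    """
    if clip.n_channels != 1:
        raise ValueError("thermal path expects a single-channel clip")
    t = clip.n_frames
    if n_samples >= t:
        idx = np.arange(t)
    else:
        idx = np.unique(np.floor(np.linspace(0, t - 1, n_samples)).astype(int))
    avg = clip.frames[idx, :, :, 0].mean(axis=0)
    span = np.ptp(avg)
    if span == 0:
        raise DegenerateImageError("constant thermal image; threshold undefined")
    norm = (avg - avg.min()) / span
    blurred = ndimage.uniform_filter(norm, size=5, mode="nearest")
    if np.ptp(blurred) == 0:
        raise DegenerateImageError("blurred thermal image is constant")
    mask = blurred > threshold_otsu(blurred)
    if not mask.any():
        raise DegenerateImageError("empty thermal face mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    roi = ROIBox(
        x0=int(cols[0]),
        y0=int(rows[0]),
        width=int(cols[-1] - cols[0] + 1),
        height=int(rows[-1] - rows[0] + 1),
    )
    return mask, roi


def square_box(roi: ROIBox, frame_h: int, frame_w: int) -> ROIBox:
    """Expand (or shrink) a box to a square that fits inside the frame.

    The dual-resolution reshaping stage requires square crops; the square is
    centered on the original box.
    """
    side = min(max(roi.width, roi.height), frame_h, frame_w)
    cx = roi.x0 + roi.width / 2
    cy = roi.y0 + roi.height / 2
    x0 = int(round(cx - side / 2))
    y0 = int(round(cy - side / 2))
    x0 = min(max(x0, 0), frame_w - side)
    y0 = min(max(y0, 0), frame_h - side)
    return ROIBox(x0=x0, y0=y0, width=side, height=side)


def crop_clip(clip: VideoClip, roi: ROIBox) -> VideoClip:
    """Crop all frames of a clip to one box (the averaged ROI)."""
    roi = roi.clipped(clip.height, clip.width)
    frames = clip.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return clip.with_frames(frames)
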