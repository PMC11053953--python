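"""Skin segmentation and head-movement rejection.

The final binary skin mask for a clip is built from every 10th frame:

1. person/background separation by a pluggable semantic-segmentation
   backend (any callable ``frame -> bool mask``; the default thresholds the
   scene with Otsu, which suffices for a dark-background recording booth);
2. 2-means binarization of the blue channel inside the person mask — the
   larger cluster is taken as skin, since facial skin dominates the
   segmented area in a chin-mounted setup;
3. removal of the bright chin stand with a static gray-level threshold
   (>= 185 counts as stand);
4. logical AND of the per-frame skin masks across the sampled frames;
5. morphological opening with a 10 x 10 square structuring element.

Clips in which the subject moved are rejected when the AND of the per-frame
masks covers less than 35% of the frame (``sum(mask)/(H*W) < 0.35``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import opening as _sk_opening
from sklearn.cluster import KMeans

from .exceptions import (
    DegenerateImageError,
    EmptySkinMaskError,
    SegmentationBackendError,
)
from .video_io import VideoClip

__all__ = [
    "SkinMask",
    "border_background_backend",
    "otsu_person_backend",
    "segment_person",
    "binarize_skin_kmeans",
    "chin_stand_mask",
    "morphological_opening",
    "per_frame_skin_masks",
    "combine_skin_mask",
    "motion_filter",
    "apply_mask",
]

PersonBackend = Callable[[np.ndarray], np.ndarray]

CHIN_STAND_THRESHOLD = 185


@dataclass
class SkinMask:
    """Final binary skin map for a clip."""

    mask: np.ndarray  # bool (H, W)
    frame_indices_used: tuple[int, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def coverage(self) -> float:
        """Fraction of frame pixels classified as skin."""
        return float(self.mask.mean())


def otsu_person_backend(frame: np.ndarray) -> np.ndarray:
    """Otsu-foreground person segmenter (for strongly bimodal scenes)."""
    gray = frame.mean(axis=-1) if frame.ndim == 3 else np.asarray(frame, dtype=float)
    if np.ptp(gray) == 0:
        return np.zeros(gray.shape, dtype=bool)
    return gray > threshold_otsu(gray)


def border_background_backend(frame: np.ndarray, border: int = 2,
                              percentile: float = 20.0,
                              offset: float = 15.0) -> np.ndarray:
    """Default person segmenter for a fixed-camera recording booth.

    Estimates the background gray level as a low percentile of the frame
    border (the darkest border pixels are background even when hair or the
    chin stand touch the frame edge after ROI cropping) and labels as person
    every pixel more than ``offset`` gray levels above it.  Keeps multi-level
    foregrounds (hair, skin, chin stand) intact, unlike a global two-class
    threshold.  Real deployments plug in a trained semantic segmenter.
    """
    gray = frame.mean(axis=-1) if frame.ndim == 3 else np.asarray(frame, dtype=float)
    ring = np.concatenate([
        gray[:border].ravel(), gray[-border:].ravel(),
        gray[border:-border, :border].ravel(), gray[border:-border, -border:].ravel(),
    ])
    background = np.percentile(ring, percentile)
    return gray > background + offset


def segment_person(frame: np.ndarray, backend: PersonBackend | None = None) -> np.ndarray:
    """Person (1) vs background (0) mask via the pluggable backend."""
    backend = backend or border_background_backend
    try:
        mask = np.asarray(backend(frame))
    except Exception as exc:  # surface backend failures with a diagnostic
        raise SegmentationBackendError(f"person-segmentation backend failed: {exc}") from exc
    if mask.shape != frame.shape[:2]:
        raise SegmentationBackendError(
            f"backend returned shape {mask.shape}, expected {frame.shape[:2]}"
        )
    return mask.astype(bool)


def binarize_skin_kmeans(
    frame_blue: np.ndarray, person_mask: np.ndarray, seed: int = 0
) -> np.ndarray:
    """2-means binarization of blue-channel intensities within the person mask.

    The cluster with the larger pixel count is labeled skin.  Raises
    :class:`DegenerateImageError` when the person region has fewer than two
    distinct intensities (clustering undefined).
    """
    person_mask = person_mask.astype(bool)
    if not person_mask.any():
        raise DegenerateImageError("empty person mask")
    values = np.asarray(frame_blue, dtype=float)[person_mask]
    if np.unique(values).size < 2:
        raise DegenerateImageError("constant person region; 2-means undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    skin_cluster = int(np.bincount(labels, minlength=2).argmax())
    mask = np.zeros(person_mask.shape, dtype=bool)
    mask[person_mask] = labels == skin_cluster
    return mask


def chin_stand_mask(frame_ref: np.ndarray, threshold: float = CHIN_STAND_THRESHOLD) -> np.ndarray:
    """1 where the pixel is NOT chin stand (gray level < threshold).

    Multiplying by this mask removes the bright stand; a pixel exactly at
    the threshold counts as stand (removed).
    """
    return np.asarray(frame_ref) < threshold


def morphological_opening(mask: np.ndarray, size: int = 10) -> np.ndarray:
    """Binary opening with a ``size x size`` square structuring element.

    The mask is zero-padded before the library call so the result equals the
    mathematical opening on a finite domain (union of all square placements
    fully contained in the mask), independent of border conventions.
    """
    if size <= 1:
        return mask.astype(bool)
    padded = np.pad(mask.astype(bool), size, mode="constant", constant_values=False)
    opened = _sk_opening(padded, footprint=np.ones((size, size), dtype=bool))
    return opened[size:-size, size:-size]


def per_frame_skin_masks(
    clip: VideoClip,
    sample_stride: int = 10,
    chin_threshold: float = CHIN_STAND_THRESHOLD,
    seed: int = 0,
    backend: PersonBackend | None = None,
    reference_channel: str = "B",
) -> tuple[list[np.ndarray], tuple[int, ...]]:
    """Per-sampled-frame skin masks (person ∧ k-means skin ∧ not-chin-stand).

    Sampled frame indices are ``0, stride, 2*stride, ...`` (12 frames for a
    120-frame clip at the default stride of 10).
    """
    ci = clip.channel_index(reference_channel) if clip.n_channels == 3 else 0
    indices = tuple(range(0, clip.n_frames, sample_stride))
    masks = []
    for ti in indices:
        frame = clip.frames[ti]
        ref = frame[..., ci]
        person = segment_person(frame, backend=backend)
        skin = binarize_skin_kmeans(ref, person, seed=seed)
        masks.append(skin & chin_stand_mask(ref, chin_threshold))
    return masks, indices


def combine_skin_mask(
    clip: VideoClip,
    sample_stride: int = 10,
    opening_size: int = 10,
    seed: int = 0,
    chin_threshold: float = CHIN_STAND_THRESHOLD,
    backend: PersonBackend | None = None,
) -> SkinMask:
    """Final clip-level skin mask: AND over sampled frames, then opening.

    Raises :class:`EmptySkinMaskError` when no pixel survives.
    """
    masks, indices = per_frame_skin_masks(
        clip,
        sample_stride=sample_stride,
        chin_threshold=chin_threshold,
        seed=seed,
        backend=backend,
    )
    combined = np.logical_and.reduce(masks)
    if not combined.any():
        raise EmptySkinMaskError("no pixel classified as skin in all sampled frames")
    final = morphological_opening(combined, opening_size)
    if not final.any():
        raise EmptySkinMaskError(
            f"skin mask empty after {opening_size}x{opening_size} opening"
        )
    return SkinMask(mask=final, frame_indices_used=indices)


def motion_filter(
    masks: Sequence[np.ndarray],
    height: int | None = None,
    width: int | None = None,
    threshold: float = 0.35,
) -> tuple[bool, float]:
    """Head-movement rejection rule.

    The overlap mask is the AND of all per-frame skin masks; the clip is
    rejected when its area fraction ``sum(mask) / (H * W)`` falls below
    ``threshold`` (35% by default, an empirical setting).

    Returns ``(keep, overlap_ratio)``.
    """
    if len(masks) < 2:
        raise ValueError("motion_filter needs at least 2 per-frame masks")
    overlap = np.logical_and.reduce([np.asarray(m, dtype=bool) for m in masks])
    h = height if height is not None else overlap.shape[0]
    w = width if width is not None else overlap.shape[1]
    ratio = float(overlap.sum()) / float(h * w)
    return ratio >= threshold, ratio


def apply_mask(clip: VideoClip, mask: SkinMask | np.ndarray) -> VideoClip:
    """Zero out non-skin pixels in every frame and channel."""
    m = mask.mask if isinstance(mask, SkinMask) else np.asarray(mask, dtype=bool)
    if m.shape != (clip.height, clip.width):
        raise ValueError(f"mask shape {m.shape} != frame shape {(clip.height, clip.width)}")
    frames = clip.frames * m[None, :, :, None].astype(clip.frames.dtype)
    return clip.with_frames(frames)
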