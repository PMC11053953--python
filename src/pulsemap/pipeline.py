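"""End-to-end feature extraction: clip in, feature blocks out.

Chains the stages in study order — face ROI detection and square cropping,
skin segmentation, head-movement check, heart-rate estimation, dual
resolution reshaping, peak/trough detection, pulsatile stack sampling and
feature-map computation — returning everything a classifier (or a test)
needs from one clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .face_detection import Detector, crop_clip, detect_face_roi_reflective, square_box
from .features import FeatureBlock, feature_ac, feature_ratio
from .hr_estimation import BandpassSpec, EHRResult, FrequencyMap, estimate_clip_hr
from .pulsatile import (
    detect_peaks_troughs,
    extract_stacks,
    reshape_high_res,
    reshape_low_res,
    upsample_indices,
)
from .skin_segmentation import (
    PersonBackend,
    SkinMask,
    apply_mask,
    combine_skin_mask,
    motion_filter,
    per_frame_skin_masks,
)
from .video_io import VideoClip

__all__ = ["ClipFeatures", "extract_clip_features", "cohort_feature_set"]


@dataclass
class ClipFeatures:
    """Per-clip pipeline outputs."""

    features: dict[tuple[str, str], FeatureBlock]  # (kind, channel) -> block
    ehr: EHRResult
    frequency_map: FrequencyMap
    skin_mask: SkinMask
    motion_keep: bool
    motion_overlap: float
    meta: dict = field(default_factory=dict)


def extract_clip_features(
    clip: VideoClip,
    channels: Sequence[str] = ("G",),
    kinds: Sequence[str] = ("AC",),
    spec: BandpassSpec | None = None,
    detector: Detector | None = None,
    person_backend: PersonBackend | None = None,
    sample_stride: int = 10,
    seed: int = 0,
    detect_face: bool = True,
    high_side: int = 224,
    low_side: int = 56,
) -> ClipFeatures:
    """Run the full feature pipeline on one reflective-modality clip.

    Returns the requested feature blocks (``kinds`` from {"AC", "R"} per
    wavelength channel) together with the EHR, skin mask and the
    head-movement decision.  The clip is *not* discarded on a motion
    rejection — the flag is reported so the caller can filter, matching the
    dataset-curation stage.
    """
    spec = spec or BandpassSpec()
    if detect_face:
        roi = square_box(
            detect_face_roi_reflective(clip, sample_stride, detector),
            clip.height,
            clip.width,
        )
        clip = crop_clip(clip, roi)

    skin = combine_skin_mask(
        clip, sample_stride=sample_stride, seed=seed, backend=person_backend
    )
    frame_masks, _ = per_frame_skin_masks(
        clip, sample_stride=sample_stride, seed=seed, backend=person_backend
    )
    keep, overlap = motion_filter(frame_masks, clip.height, clip.width)

    masked = apply_mask(clip, skin)
    ehr, fmap = estimate_clip_hr(masked, skin.mask, spec=spec)

    low = reshape_low_res(masked, side=low_side)
    high = reshape_high_res(masked, side=high_side)
    factor = high_side // low_side

    blocks: dict[tuple[str, str], FeatureBlock] = {}
    min_distance = None
    for channel in channels:
        idx = detect_peaks_troughs(low, channel, ehr, spec)
        min_distance = idx.min_distance
        peaks_hi = upsample_indices(idx.peak_idx, factor)
        troughs_hi = upsample_indices(idx.trough_idx, factor)
        stack = extract_stacks(high, peaks_hi, troughs_hi, channel)
        for kind in kinds:
            if kind == "AC":
                blocks[("AC", channel)] = feature_ac(stack)
            elif kind == "R":
                blocks[("R", channel)] = feature_ratio(stack)
            else:
                raise ValueError(f"unknown feature kind {kind!r}")

    return ClipFeatures(
        features=blocks,
        ehr=ehr,
        frequency_map=fmap,
        skin_mask=skin,
        motion_keep=keep,
        motion_overlap=overlap,
        meta={"source_id": clip.source_id, "min_distance": min_distance},
    )


def cohort_feature_set(
    cohort,
    channel: str = "G",
    kind: str = "AC",
    seed: int = 0,
    drop_motion_rejected: bool = True,
    on_error: str = "raise",
    **kwargs,
):
    """Run the feature pipeline over a cohort of (clip, truth) pairs.

    Returns a :class:`~pulsemap.harness.LabeledFeatureSet` of one feature
    block per retained clip, labeled with the ground-truth emotion class and
    subject identity.  Clips failing the head-movement rule are dropped by
    default, mirroring dataset curation.  With ``on_error='skip'``, clips on
    which a pipeline stage fails (e.g. an empty skin mask) are excluded the
    same way a curation pass would drop them, instead of aborting the run.
    """
    from .exceptions import PulsemapError
    from .harness import LabeledFeatureSet  # local import to avoid a cycle

    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    blocks, labels, subjects = [], [], []
    n_failed = 0
    for clip, truth in cohort:
        try:
            result = extract_clip_features(
                clip, channels=(channel,), kinds=(kind,), seed=seed, **kwargs
            )
        except PulsemapError:
            if on_error == "raise":
                raise
            n_failed += 1
            continue
        if drop_motion_rejected and not result.motion_keep:
            continue
        blocks.append(result.features[(kind, channel)].values.astype(np.float32))
        labels.append(truth.class_label)
        subjects.append(truth.subject_id)
    data = LabeledFeatureSet(
        blocks=np.stack(blocks), labels=labels, subject_ids=subjects
    )
    data.n_failed = n_failed
    return data
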