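"""Synthetic facial-video generator with known ground truth.

Real multispectral emotion datasets are rarely shareable (facial videos),
so every downstream stage here is exercised on synthetic clips built from
the Beer-Lambert reflectance model of skin,

.. math::

    I_\\lambda(t) = I_{0,\\lambda}\\,\\bigl(e^{-(A_{DC,\\lambda}
        + A_{pulsatile,\\lambda}(x,y)\\, s(t))} + R_{S,\\lambda}\\bigr),

where :math:`I_0` is the incident intensity, :math:`A_{DC}` the static
absorbance of non-varying absorbers (tissue, bone, average blood volume),
:math:`A_{pulsatile}` the per-pixel absorbance swing driven by the blood
volume pulse, :math:`s(t)` a unit periodic pulse waveform at the heart
frequency :math:`f_0`, and :math:`R_S` a specular (pulse-free) reflection
fraction.  Reflected intensity therefore *peaks* when absorbance is minimal
(:math:`s=-1`, diastole) and bottoms out at :math:`s=+1` (systole).

A scene is a centered elliptical "face" of skin on a dark background, with
an optional bright chin-stand rectangle at the bottom edge (gray level well
above the 185 removal threshold) and optional rigid integer-pixel head
translation.  Gaussian camera noise and 8-bit quantization are applied last.

Default amplitudes: the pulse modulates the green channel strongest
(B:G:R amplitude ratios 0.7 : 1.0 : 0.5, reflecting hemoglobin absorption
and sensor SNR), with a baseline absorbance swing of 0.02 around a diffuse
level near 130 gray levels, i.e. a peak-to-peak pulsatile excursion of
roughly 5 gray levels in G — a deliberately "easy but honest" SNR regime of
a few dB per pixel at the default noise of 1 gray level.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .video_io import VideoClip

__all__ = [
    "SceneGeometry",
    "SyntheticSkinModel",
    "SyntheticClipTruth",
    "generate_synthetic_clip",
    "generate_cohort",
    "annular_class_templates",
    "identical_class_templates",
    "EMOTION_CLASSES",
]

EMOTION_CLASSES: tuple[str, ...] = ("A", "D", "F", "S", "N")

DEFAULT_CHANNEL_AMPLITUDE_RATIOS: dict[str, float] = {
    "B": 0.7,
    "G": 1.0,
    "R": 0.5,
    "NIR": 0.35,
    "LWIR": 0.0,
}


@dataclass
class SceneGeometry:
    """Spatial layout of a synthetic scene."""

    height: int = 120
    width: int = 120
    face_center: tuple[float, float] | None = None  # (row, col); default = frame center
    face_axes: tuple[float, float] | None = None  # (semi_r, semi_c); default 0.38*H, 0.30*W
    background_level: float = 40.0
    # non-skin person region (hair/collar crescent around the upper face);
    # gives the skin/non-skin clustering its real second class
    hair: bool = True
    hair_level: float = 65.0
    hair_scale: float = 1.3
    chin_stand: bool = False
    chin_stand_level: float = 230.0
    chin_stand_rows: int = 12  # height of the stand band at the bottom edge
    chin_stand_halfwidth: float = 0.22  # fraction of W on each side of center
    # total rigid translation (rows, cols) ramped linearly over the clip
    motion_shift: tuple[int, int] = (0, 0)

    def face_mask(self) -> np.ndarray:
        cy, cx = self.face_center or ((self.height - 1) / 2, (self.width - 1) / 2)
        ry, rx = self.face_axes or (0.38 * self.height, 0.30 * self.width)
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        return np.nan_to_num(rho, nan=np.inf) <= 1.0

    def hair_mask(self) -> np.ndarray:
        if not self.hair:
            return np.zeros((self.height, self.width), dtype=bool)
        cy, cx = self.face_center or ((self.height - 1) / 2, (self.width - 1) / 2)
        ry, rx = self.face_axes or (0.38 * self.height, 0.30 * self.width)
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        outer = ((yy - cy) / (ry * self.hair_scale)) ** 2 + (
            (xx - cx) / (rx * self.hair_scale)
        ) ** 2 <= 1.0
        crescent = outer & ~self.face_mask() & (yy <= cy + 0.3 * ry)
        return crescent

    def chin_stand_mask(self) -> np.ndarray:
        mask = np.zeros((self.height, self.width), dtype=bool)
        if self.chin_stand:
            half = int(round(self.chin_stand_halfwidth * self.width))
            c0 = self.width // 2 - half
            c1 = self.width // 2 + half
            mask[self.height - self.chin_stand_rows :, max(c0, 0) : c1] = True
        return mask


@dataclass
class SyntheticSkinModel:
    """Optical and temporal parameters of the skin reflectance model."""

    incident_intensity: float = 220.0  # I0, gray-level scale
    static_absorbance: float = 0.5  # A_DC, unitless
    pulsatile_amplitude: float | np.ndarray = 0.02  # A_pulsatile, scalar or (H, W)
    specular_fraction: float = 0.05  # R_S in [0, 1)
    pulse_frequency_hz: float = 1.2  # f0
    pulse_phase: float = 0.0  # phi0, radians
    noise_sd: float = 1.0  # gray levels
    quantize: bool = True
    waveform: str = "sinusoid"  # or "ppg" (fast systolic rise)
    channel_amplitude_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_AMPLITUDE_RATIOS)
    )

    def pulse_waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit pulse waveform ``s(t)`` (max |s| = 1) at ``f0``."""
        theta = 2 * math.pi * self.pulse_frequency_hz * t + self.pulse_phase
        if self.waveform == "sinusoid":
            return np.sin(theta)
        if self.waveform == "ppg":
            # asymmetric PPG-like absorbance: sharp systolic rise, slow decay
            raw = np.sin(theta) + 0.35 * np.sin(2 * theta + 0.9)
            return raw / np.max(np.abs(raw))
        raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass
class SyntheticClipTruth:
    """Ground truth attached to a generated clip."""

    true_hr_hz: float
    skin_mask: np.ndarray  # bool (H, W), frame-0 position
    peak_times: np.ndarray  # frame indices of reflected-intensity maxima
    trough_times: np.ndarray  # frame indices of reflected-intensity minima
    amplitude_map: np.ndarray  # per-pixel base absorbance swing (H, W)
    channel_amplitude_ratios: dict[str, float] = field(default_factory=dict)
    class_label: str = "N"
    subject_id: str = ""


def _reflectance(model: SyntheticSkinModel, absorbance: np.ndarray | float) -> np.ndarray:
    return model.incident_intensity * (np.exp(-np.asarray(absorbance, dtype=float))
                                       + model.specular_fraction)


def _strict_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D sequence."""
    interior = np.arange(1, len(x) - 1)
    maxima = interior[(x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])]
    minima = interior[(x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])]
    return maxima, minima


def generate_synthetic_clip(
    model: SyntheticSkinModel,
    geometry: SceneGeometry | None = None,
    duration_frames: int = 120,
    fps: float = 30.0,
    seed: int = 0,
    channel_labels: Sequence[str] = ("B", "G", "R"),
) -> tuple[VideoClip, SyntheticClipTruth]:
    """Generate one synthetic facial clip plus its ground truth.

    Skin pixels oscillate at ``model.pulse_frequency_hz`` with per-pixel
    absorbance amplitude; background and chin-stand pixels carry no pulse.
    Identical seeds and parameters reproduce identical clips bit-for-bit.

    Raises
    ------
    ValueError
        If ``fps <= 2 * f0`` (the pulse would alias) or the skin geometry
        is empty.
    """
    geometry = geometry or SceneGeometry()
    if duration_frames < 2:
        raise ValueError("duration_frames must be >= 2")
    if not fps > 2 * model.pulse_frequency_hz:
        raise ValueError(
            f"fps={fps} violates the Nyquist bound for f0={model.pulse_frequency_hz} Hz"
        )
    skin = geometry.face_mask()
    if not skin.any():
        raise ValueError("empty skin geometry")

    amp = np.broadcast_to(
        np.asarray(model.pulsatile_amplitude, dtype=float),
        (geometry.height, geometry.width),
    ).copy()
    amp[~skin] = 0.0

    rng = np.random.default_rng(seed)
    t = np.arange(duration_frames) / fps
    s = model.pulse_waveform(t)

    stand = geometry.chin_stand_mask()
    hair = geometry.hair_mask() & ~skin
    # the stand occludes the lower face: ground-truth skin is the visible part
    skin = skin & ~stand
    if not skin.any():
        raise ValueError("chin stand occludes the entire face")
    amp[~skin] = 0.0
    background = np.full((geometry.height, geometry.width), geometry.background_level)
    ratios = {k.upper(): v for k, v in model.channel_amplitude_ratios.items()}

    frames = np.empty(
        (duration_frames, geometry.height, geometry.width, len(channel_labels)),
        dtype=float,
    )
    for ci, label in enumerate(channel_labels):
        ratio = ratios.get(label.upper(), 1.0)
        # (T, H, W) absorbance, then Beer-Lambert reflectance
        absorb = model.static_absorbance + ratio * amp[None, :, :] * s[:, None, None]
        chan = _reflectance(model, absorb)
        chan = np.where(skin[None], chan, background[None])
        chan = np.where(hair[None], geometry.hair_level, chan)
        chan = np.where(stand[None], geometry.chin_stand_level, chan)
        frames[..., ci] = chan

    dy_total, dx_total = geometry.motion_shift
    if dy_total or dx_total:
        ramp = np.linspace(0.0, 1.0, duration_frames)
        for ti in range(duration_frames):
            dy = int(round(dy_total * ramp[ti]))
            dx = int(round(dx_total * ramp[ti]))
            if dy or dx:
                frames[ti] = ndimage.shift(
                    frames[ti], (dy, dx, 0), order=0, mode="constant",
                    cval=geometry.background_level,
                )

    if model.noise_sd > 0:
        frames = frames + rng.normal(0.0, model.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 255.0)
    if model.quantize:
        frames = np.round(frames).astype(np.uint8)
    else:
        frames = frames.astype(np.float32)

    # ground-truth extrema of the noiseless reflected-intensity waveform:
    # intensity is maximal where absorbance (hence s) is minimal
    ref = _reflectance(model, model.static_absorbance + float(np.max(amp)) * s)
    peaks, troughs = _strict_extrema(ref)

    clip = VideoClip(
        frames=frames,
        fps=fps,
        channel_labels=tuple(channel_labels),
        source_id=f"synthetic(f0={model.pulse_frequency_hz:.3f}Hz,seed={seed})",
    )
    truth = SyntheticClipTruth(
        true_hr_hz=model.pulse_frequency_hz,
        skin_mask=skin,
        peak_times=peaks,
        trough_times=troughs,
        amplitude_map=amp,
        channel_amplitude_ratios=dict(ratios),
    )
    return clip, truth


# ---------------------------------------------------------------------------
# class-effect templates and cohort generation
# ---------------------------------------------------------------------------

def annular_class_templates(
    geometry: SceneGeometry,
    labels: Sequence[str] = EMOTION_CLASSES,
    baseline: float = 0.3,
    peak: float = 1.3,
) -> dict[str, np.ndarray]:
    """Disjoint concentric-annulus amplitude templates, one per class.

    Each template multiplies the base pulsatile amplitude: ``baseline``
    everywhere on the face and ``peak`` inside the class's annulus.  Annuli
    are concentric with the face ellipse, so the class-specific region is
    invariant under the 90/180/270-degree rotations used for training
    augmentation (quadrant-style regions would alias across classes there).
    """
    cy, cx = geometry.face_center or ((geometry.height - 1) / 2, (geometry.width - 1) / 2)
    ry, rx = geometry.face_axes or (0.38 * geometry.height, 0.30 * geometry.width)
    yy, xx = np.mgrid[0 : geometry.height, 0 : geometry.width]
    rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)  # 0 center, 1 rim
    edges = np.linspace(0.0, 1.0, len(labels) + 1)
    templates = {}
    for k, label in enumerate(labels):
        band = (rho >= edges[k]) & (rho < edges[k + 1])
        templates[label] = np.where(band, peak, baseline)
    return templates


def identical_class_templates(
    geometry: SceneGeometry, labels: Sequence[str] = EMOTION_CLASSES
) -> dict[str, np.ndarray]:
    """Null-signal templates: every class shares the same uniform pattern."""
    ones = np.ones((geometry.height, geometry.width))
    return {label: ones for label in labels}


def generate_cohort(
    n_subjects: int,
    clips_per_subject: int,
    class_effect: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
    geometry: SceneGeometry | None = None,
    duration_frames: int = 120,
    fps: float = 30.0,
    hr_range_hz: tuple[float, float] = (0.9, 3.0),
    base_amplitude: float = 0.02,
    noise_sd: float = 1.0,
    chin_stand_fraction: float = 0.5,
) -> list[tuple[VideoClip, SyntheticClipTruth]]:
    """Generate a cohort of clips emulating a multi-subject recording study.

    Each subject gets its own baseline skin tone (static absorbance and
    incident intensity) and heart rate drawn from ``hr_range_hz``; clip
    labels cycle through the five emotion classes so the cohort is balanced
    up to a remainder.  ``class_effect`` maps labels to per-pixel amplitude
    templates (multipliers of ``base_amplitude``); by default all classes
    share a uniform template (no class signal).  Roughly half the subjects
    are recorded with a bright chin stand, exercising its removal rule.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    geometry = geometry or SceneGeometry(height=80, width=80)
    if class_effect is None:
        class_effect = identical_class_templates(geometry)
    unknown = set(class_effect) - set(EMOTION_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)}")
    missing = [c for c in EMOTION_CLASSES if c not in class_effect]
    if missing:
        raise ValueError(f"class_effect missing labels {missing}")

    rng = np.random.default_rng(seed)
    cohort: list[tuple[VideoClip, SyntheticClipTruth]] = []
    for si in range(n_subjects):
        subject_id = f"S{si:03d}"
        a_dc = rng.uniform(0.35, 0.7)
        i0 = rng.uniform(190.0, 240.0)
        f0 = rng.uniform(*hr_range_hz)
        with_stand = rng.random() < chin_stand_fraction
        geo = dataclasses.replace(geometry, chin_stand=with_stand)
        for ci in range(clips_per_subject):
            label = EMOTION_CLASSES[ci % len(EMOTION_CLASSES)]
            model = SyntheticSkinModel(
                incident_intensity=i0,
                static_absorbance=a_dc,
                pulsatile_amplitude=base_amplitude * np.asarray(class_effect[label]),
                pulse_frequency_hz=f0,
                pulse_phase=float(rng.uniform(0, 2 * math.pi)),
                noise_sd=noise_sd,
            )
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip, truth = generate_synthetic_clip(
                model, geo, duration_frames=duration_frames, fps=fps, seed=clip_seed
            )
            truth.class_label = label
            truth.subject_id = subject_id
            clip.source_id = f"{subject_id}/clip{ci:03d}/{label}"
            cohort.append((clip, truth))
    return cohort
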