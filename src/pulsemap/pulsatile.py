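"""Dual-resolution reshaping and pulsatile image-stack extraction.

The square-cropped face clip is scaled to two resolutions:

* 56 x 56 (low): block averaging (10 x 10 for RGB, 5 x 5 for NIR) followed
  by bi-cubic interpolation — averaging the temporal signals of each small
  neighborhood suppresses quantization noise, improving the per-pixel
  pulsatile signal;
* 224 x 224 (high): 2 x 2 block averaging for RGB, then bi-cubic
  interpolation for all modalities — preserving spatial detail at a standard
  network input size.

Heartbeat peak/trough times are found per low-resolution pixel on the
band-passed signal with a minimum peak separation of

.. math:: d = \\lfloor \\tfrac{3}{4}\\, T_{HR} / T_S \\rfloor

samples (three quarters of a heartbeat period), troughs being peaks of the
negated signal.  Up to 5 peak and 5 trough indices are stored per pixel
(padded when fewer exist; sentinel -1 internally, exported as zero padding
with a validity mask, because frame index 0 is a legal peak time).  Index
arrays are upsampled 56 -> 224 by nearest-neighbor repetition (each location
copied to its 4 x 4 block) and used to sample the high-resolution frames
into the pulsatile image stacks ``I_max`` / ``I_min`` of shape 224 x 224 x 5.

The thermal (LWIR) channel carries no usable heartbeat information; its
stack is simply 5 uniformly sampled frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from functools import lru_cache

from scipy import signal as sps

from .exceptions import NonSquareClipError
from .hr_estimation import BandpassSpec, EHRResult, bandpass_filter, block_downsample
from .video_io import VideoClip

__all__ = [
    "PeakTroughIndex",
    "PulsatileStack",
    "min_peak_distance",
    "reshape_low_res",
    "reshape_high_res",
    "detect_peaks_troughs",
    "upsample_indices",
    "extract_stacks",
    "lwir_uniform_stack",
    "N_PULSATILE_FRAMES",
]

N_PULSATILE_FRAMES = 5
PAD = -1  # internal pad sentinel; exported arrays zero-pad with a validity mask


@dataclass
class PeakTroughIndex:
    """Per-pixel heartbeat peak/trough frame indices (pad = -1)."""

    peak_idx: np.ndarray  # (h, w, 5) int
    trough_idx: np.ndarray  # (h, w, 5) int
    min_distance: int  # d, samples

    @property
    def peak_valid(self) -> np.ndarray:
        return self.peak_idx != PAD

    @property
    def trough_valid(self) -> np.ndarray:
        return self.trough_idx != PAD

    def zero_padded(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays with pads exported as 0 (alongside the validity masks)."""
        return (
            np.where(self.peak_valid, self.peak_idx, 0),
            np.where(self.trough_valid, self.trough_idx, 0),
        )


@dataclass
class PulsatileStack:
    """Paired peak/trough image stacks for one wavelength channel."""

    i_max: np.ndarray  # (H, W, 5) gray levels, 0 at padded positions
    i_min: np.ndarray  # (H, W, 5)
    valid_max: np.ndarray  # (H, W, 5) bool
    valid_min: np.ndarray  # (H, W, 5) bool
    channel: str = "G"


def min_peak_distance(ehr: EHRResult, fs: float) -> int:
    """Minimum peak separation ``d = floor(0.75 * T_HR / T_S)``, at least 1."""
    return max(1, int(np.floor(0.75 * ehr.t_hr * fs)))


def _keys_cubic(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (the classic bi-cubic weights)."""
    ax = np.abs(x)
    w = np.zeros_like(ax)
    inner = ax <= 1
    outer = (ax > 1) & (ax < 2)
    w[inner] = (a + 2) * ax[inner] ** 3 - (a + 3) * ax[inner] ** 2 + 1
    w[outer] = a * (ax[outer] ** 3 - 5 * ax[outer] ** 2 + 8 * ax[outer] - 4)
    return w


@lru_cache(maxsize=32)
def _cubic_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) separable bi-cubic interpolation weights.

    Pixel-center coordinate mapping with edge replication (out-of-range taps
    clamp to the border pixel).  Rows sum to 1, so constants are preserved.
    """
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    base = np.floor(src).astype(int)
    mat = np.zeros((n_out, n_in))
    for tap in range(-1, 3):
        idx = base + tap
        w = _keys_cubic(src - idx)
        np.add.at(mat, (np.arange(n_out), np.clip(idx, 0, n_in - 1)), w)
    return mat


def _resize_frames(frames: np.ndarray, side: int) -> np.ndarray:
    """Bi-cubic spatial resize of a (T, h, w[, C]) stack to side x side."""
    if frames.ndim == 3:
        frames = frames[..., np.newaxis]
    my = _cubic_resize_matrix(frames.shape[1], side)
    mx = _cubic_resize_matrix(frames.shape[2], side)
    out = np.einsum("ij,tjwc->tiwc", my, frames, optimize=True)
    return np.einsum("kw,tiwc->tikc", mx, out, optimize=True)


def _reshape(clip: VideoClip, side: int, block: int | None) -> VideoClip:
    if clip.height != clip.width:
        raise NonSquareClipError(
            f"square-cropped clip required; got {clip.height}x{clip.width}"
        )
    frames = np.asarray(clip.frames, dtype=float)
    if block and block > 1:
        frames = block_downsample(frames, block)
    return clip.with_frames(_resize_frames(frames, side).astype(np.float32))


def reshape_low_res(clip: VideoClip, side: int = 56, block: int | None = None) -> VideoClip:
    """Low-resolution (56 x 56) clip: block averaging then bi-cubic resize.

    Default block is 10 x 10 for 3-channel (RGB) clips and 5 x 5 for
    single-channel (NIR) clips, whose native resolution is smaller.
    """
    if block is None:
        block = 10 if clip.n_channels == 3 else 5
    return _reshape(clip, side, block)


def reshape_high_res(clip: VideoClip, side: int = 224) -> VideoClip:
    """High-resolution (224 x 224) clip: 2 x 2 averaging (RGB only), bi-cubic."""
    block = 2 if clip.n_channels == 3 else 1
    return _reshape(clip, side, block)


def _select_five(idx: np.ndarray, heights: np.ndarray, keep: str) -> np.ndarray:
    """Keep at most 5 detections: first-in-time (default) or highest."""
    if idx.size <= N_PULSATILE_FRAMES:
        kept = idx
    elif keep == "first":
        kept = idx[:N_PULSATILE_FRAMES]
    elif keep == "highest":
        top = np.sort(np.argsort(heights)[::-1][:N_PULSATILE_FRAMES])
        kept = idx[top]
    else:
        raise ValueError(f"keep must be 'first' or 'highest', not {keep!r}")
    out = np.full(N_PULSATILE_FRAMES, PAD, dtype=np.int64)
    out[: kept.size] = kept
    return out


def detect_peaks_troughs(
    lowres_clip: VideoClip,
    channel: str,
    ehr: EHRResult,
    spec: BandpassSpec | None = None,
    keep: str = "first",
    flat_tol: float = 1e-6,
) -> PeakTroughIndex:
    """Per-pixel peak/trough detection on the band-passed low-res signal.

    Peaks are strict local maxima separated by at least ``d`` samples
    (conflicts resolved greedily in favor of higher peaks); troughs are the
    peaks of the negated signal with the same ``d``.  When more than 5
    survive, the first 5 in time are stored by default (``keep='highest'``
    switches to the 5 largest).  Pixels with no extrema (e.g. constant
    background) yield fully padded rows; a band-passed series whose total
    excursion is below ``flat_tol`` gray levels (far below one quantization
    step) is treated as flat rather than letting floating-point residue
    masquerade as a pulse.
    """
    spec = spec or BandpassSpec()
    stack = (
        lowres_clip.channel(channel)
        if lowres_clip.n_channels == 3
        else lowres_clip.frames[..., 0]
    )
    t, h, w = stack.shape
    d = min_peak_distance(ehr, lowres_clip.fps)
    if t < 2 * d:
        raise ValueError(f"clip of {t} frames too short for min distance d={d}")
    filtered = bandpass_filter(stack, lowres_clip.fps, spec, axis=0)

    peak_idx = np.full((h, w, N_PULSATILE_FRAMES), PAD, dtype=np.int64)
    trough_idx = np.full((h, w, N_PULSATILE_FRAMES), PAD, dtype=np.int64)
    for i in range(h):
        for j in range(w):
            x = filtered[:, i, j]
            if np.ptp(x) < flat_tol:
                continue
            pk, _ = sps.find_peaks(x, distance=d)
            tr, _ = sps.find_peaks(-x, distance=d)
            peak_idx[i, j] = _select_five(pk, x[pk], keep)
            trough_idx[i, j] = _select_five(tr, -x[tr], keep)
    return PeakTroughIndex(peak_idx=peak_idx, trough_idx=trough_idx, min_distance=d)


def upsample_indices(idx: np.ndarray, factor: int = 4) -> np.ndarray:
    """Nearest-neighbor index upsampling: each location fills a factor x factor block."""
    idx = np.asarray(idx)
    return np.repeat(np.repeat(idx, factor, axis=0), factor, axis=1)


def extract_stacks(
    highres_clip: VideoClip,
    peak_idx: np.ndarray,
    trough_idx: np.ndarray,
    channel: str = "G",
) -> PulsatileStack:
    """Sample the high-resolution frames at the peak/trough times.

    ``peak_idx``/``trough_idx`` are (H, W, 5) frame-index arrays on the
    high-resolution grid (pad = -1).  Pure indexing — no interpolation;
    padded positions are 0 in the stacks.
    """
    frames = (
        highres_clip.channel(channel)
        if highres_clip.n_channels == 3
        else highres_clip.frames[..., 0]
    )
    t = frames.shape[0]
    per_pixel = np.moveaxis(np.asarray(frames, dtype=float), 0, -1)  # (H, W, T)

    def gather(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(idx)
        if idx.shape[:2] != per_pixel.shape[:2] or idx.shape[2] != N_PULSATILE_FRAMES:
            raise ValueError(f"index array shape {idx.shape} does not match clip")
        valid = idx != PAD
        if np.any(idx[valid] >= t) or np.any(idx[valid] < 0):
            raise IndexError("peak/trough index out of frame range")
        values = np.take_along_axis(per_pixel, np.where(valid, idx, 0), axis=2)
        return np.where(valid, values, 0.0), valid

    i_max, valid_max = gather(peak_idx)
    i_min, valid_min = gather(trough_idx)
    return PulsatileStack(
        i_max=i_max, i_min=i_min, valid_max=valid_max, valid_min=valid_min,
        channel=channel,
    )


def lwir_uniform_stack(clip: VideoClip) -> np.ndarray:
    """Thermal stack: 5 uniformly sampled frames (no heartbeat content).

    Frame indices are ``0, floor(T/4), floor(T/2), floor(3T/4), T-1``.
    """
    if clip.n_channels != 1:
        raise ValueError("LWIR path expects a single-channel clip")
    t = clip.n_frames
    if t < N_PULSATILE_FRAMES:
        raise ValueError(f"need at least {N_PULSATILE_FRAMES} frames; got {t}")
    indices = [0, t // 4, t // 2, (3 * t) // 4, t - 1]
    return np.moveaxis(clip.frames[indices, :, :, 0].astype(float), 0, -1)
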