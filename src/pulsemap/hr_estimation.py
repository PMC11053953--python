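"""Clip-level heart-rate estimation from the green-channel skin video.

The estimated heart rate (EHR) drives the peak/trough minimum-distance rule
downstream.  Procedure:

1. spatially downsample the masked skin video by 10 x 10 block averaging
   (suppresses quantization noise in the per-pixel time series);
2. band-pass every remaining pixel's green time series with a Butterworth
   filter, 0.75-3.5 Hz (45-210 bpm, the physiological heart-rate band);
3. per pixel, take the FFT-magnitude argmax restricted to the pass band,
   giving a 2-D map of locally dominant frequencies;
4. smooth the map with a 3 x 3 spatial median filter and report the median
   of all non-zero values as the EHR.

The band-pass runs zero-phase (forward-backward), preserving extrema timing
for the later peak indexing.  FFT length equals the clip length (no padding
or window), so the frequency resolution is ``fs / T`` — 0.25 Hz for a 4 s,
30 fps clip.  Argmax ties break toward the lower frequency; medians of
even-sized multisets use the lower-median convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ClipTooShortError, EmptySkinMaskError
from .video_io import VideoClip

__all__ = [
    "BandpassSpec",
    "FrequencyMap",
    "EHRResult",
    "block_downsample",
    "bandpass_filter",
    "dominant_frequency_map",
    "estimate_heart_rate",
    "estimate_clip_hr",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass design.

    ``order`` is the overall band-pass order (6 means a 6th-order band-pass,
    i.e. 3 analog low-pass poles mapped through the band transformation).
    """

    order: int = 6
    low_hz: float = 0.75
    high_hz: float = 3.5

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"band {self.low_hz}-{self.high_hz} Hz invalid for fs={fs} Hz"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        if self.order % 2:
            raise ValueError("band-pass order must be even")
        return sps.butter(
            self.order // 2,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )


@dataclass
class FrequencyMap:
    """Per-pixel dominant temporal frequency (Hz); 0 outside the skin."""

    freq_hz: np.ndarray  # (h, w) float
    valid: np.ndarray  # (h, w) bool


@dataclass(frozen=True)
class EHRResult:
    """Estimated heart rate of one clip."""

    f_hr: float  # Hz

    def __post_init__(self) -> None:
        if not np.isfinite(self.f_hr) or self.f_hr <= 0:
            raise ValueError(f"invalid heart-rate frequency {self.f_hr}")

    @property
    def bpm(self) -> float:
        """Heart rate in beats per minute (60 * f_hr)."""
        return 60.0 * self.f_hr

    @property
    def t_hr(self) -> float:
        """Heartbeat period in seconds (1 / f_hr)."""
        return 1.0 / self.f_hr


def block_downsample(frames: np.ndarray, block: int) -> np.ndarray:
    """Average non-overlapping ``block x block`` spatial blocks.

    Works on ``(T, H, W)`` or ``(T, H, W, C)`` stacks (and on single ``(H, W)``
    images).  Output spatial dims are ``ceil(H/block) x ceil(W/block)``;
    partial edge blocks average over the pixels they actually contain.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    a = np.asarray(frames, dtype=float)
    if block == 1:
        return a.copy()
    single = a.ndim == 2
    if single:
        a = a[np.newaxis]
    h, w = a.shape[1], a.shape[2]
    row_starts = np.arange(0, h, block)
    col_starts = np.arange(0, w, block)
    sums = np.add.reduceat(np.add.reduceat(a, row_starts, axis=1), col_starts, axis=2)
    row_counts = np.diff(np.append(row_starts, h))
    col_counts = np.diff(np.append(col_starts, w))
    counts = np.multiply.outer(row_counts, col_counts).astype(float)
    if a.ndim == 4:
        counts = counts[..., np.newaxis]
    out = sums / counts
    return out[0] if single else out


def bandpass_filter(
    x: np.ndarray, fs: float, spec: BandpassSpec | None = None, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis`` (DC removed).

    Raises :class:`ClipTooShortError` when the series is shorter than
    ``3 * order`` samples (not enough room for the filter to settle).
    """
    spec = spec or BandpassSpec()
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 3 * spec.order:
        raise ClipTooShortError(f"{n} samples < 3 * order = {3 * spec.order}")
    return sps.sosfiltfilt(spec.sos(fs), x, axis=axis)


def dominant_frequency_map(
    skin_clip_green: np.ndarray,
    fs: float,
    spec: BandpassSpec | None = None,
    skin_mask_lowres: np.ndarray | None = None,
) -> FrequencyMap:
    """Per-pixel dominant in-band frequency of the band-passed time series.

    ``skin_clip_green`` is a ``(T, h, w)`` stack.  Each valid pixel maps to
    the frequency of the maximum-magnitude FFT bin restricted to the pass
    band; non-skin pixels map to exactly 0.  Ties break to the lower bin
    (``argmax`` keeps the first maximum).
    """
    spec = spec or BandpassSpec()
    stack = np.asarray(skin_clip_green, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected (T, h, w); got {stack.shape}")
    t = stack.shape[0]
    mask = (
        np.ones(stack.shape[1:], dtype=bool)
        if skin_mask_lowres is None
        else np.asarray(skin_mask_lowres, dtype=bool)
    )
    if not mask.any():
        raise EmptySkinMaskError("empty low-resolution skin mask")

    filtered = bandpass_filter(stack, fs, spec, axis=0)
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    band = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
    if not band.any():
        raise ValueError("no FFT bin falls inside the pass band; clip too short")
    mag = np.abs(np.fft.rfft(filtered, axis=0))[band]
    dominant = freqs[band][np.argmax(mag, axis=0)]
    return FrequencyMap(freq_hz=np.where(mask, dominant, 0.0), valid=mask)


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-of-the-two convention for even counts."""
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(v[(v.size - 1) // 2])


def median_filter_nonzero(
    freq: np.ndarray, kernel: int = 3, exclude_zeros: bool = True
) -> np.ndarray:
    """Spatial median filter of a frequency map.

    Zeros mark non-skin pixels, so by default each pixel's neighborhood
    median is taken over non-zero neighbors only, and zero-valued pixels stay
    zero (the map never grows).  With ``exclude_zeros=False`` a plain median
    over the full window is used.
    """
    if kernel % 2 != 1 or kernel < 1:
        raise ValueError("kernel must be odd and positive")
    pad = kernel // 2
    padded = np.pad(freq, pad, mode="constant", constant_values=0.0)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kernel, kernel))
    out = np.zeros_like(np.asarray(freq, dtype=float))
    h, w = freq.shape
    for i in range(h):
        for j in range(w):
            if freq[i, j] == 0:
                continue
            win = windows[i, j].ravel()
            vals = win[win != 0] if exclude_zeros else win
            out[i, j] = _lower_median(vals) if vals.size else 0.0
    return out


def estimate_heart_rate(
    fmap: FrequencyMap, median_kernel: int = 3, exclude_zeros: bool = True
) -> EHRResult:
    """EHR = median of the non-zero values of the median-filtered map."""
    smoothed = median_filter_nonzero(fmap.freq_hz, median_kernel, exclude_zeros)
    nonzero = smoothed[smoothed != 0]
    if nonzero.size == 0:
        raise EmptySkinMaskError("frequency map has no non-zero values")
    return EHRResult(f_hr=_lower_median(nonzero))


def estimate_clip_hr(
    clip: VideoClip,
    skin_mask: np.ndarray,
    block: int = 10,
    spec: BandpassSpec | None = None,
    channel: str = "G",
    mask_fraction: float = 0.5,
) -> tuple[EHRResult, FrequencyMap]:
    """Full EHR pipeline on a masked clip (downsample, band-pass, FFT, median).

    The low-resolution validity mask keeps blocks whose skin coverage is at
    least ``mask_fraction``.
    """
    spec = spec or BandpassSpec()
    green = clip.channel(channel) if clip.n_channels == 3 else clip.frames[..., 0]
    masked = green * skin_mask[None].astype(float)
    low = block_downsample(masked, block)
    low_mask = block_downsample(skin_mask.astype(float), block) >= mask_fraction
    if not low_mask.any():
        raise EmptySkinMaskError("skin mask vanished under block downsampling")
    fmap = dominant_frequency_map(low, clip.fps, spec, low_mask)
    return estimate_heart_rate(fmap), fmap
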