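"""Brute-force reference implementations used only by the tests.

Each oracle is deliberately naive (exhaustive search, explicit loops) and
independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_otsu_threshold(image: np.ndarray) -> float:
    """Exhaustive Otsu: the threshold maximizing between-class variance.

    Scans all midpoints between consecutive distinct values; returns the
    threshold t such that the classes are {x <= t} and {x > t}.
    """
    values = np.sort(np.unique(np.asarray(image, dtype=float).ravel()))
    if values.size < 2:
        raise ValueError("constant image")
    flat = np.asarray(image, dtype=float).ravel()
    best_t, best_var = None, -1.0
    for lo, hi in zip(values[:-1], values[1:]):
        t = (lo + hi) / 2
        c0 = flat[flat <= t]
        c1 = flat[flat > t]
        w0, w1 = c0.size / flat.size, c1.size / flat.size
        var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def brute_kmeans_1d(values: np.ndarray) -> np.ndarray:
    """Optimal 1-D 2-means by exhaustive split-point search.

    Returns a boolean array marking membership of the upper cluster.  The
    optimal 2-means partition of scalars is an interval split, so scanning
    all splits of the sorted values finds the global optimum.
    """
    v = np.asarray(values, dtype=float).ravel()
    order = np.argsort(v)
    s = v[order]
    best_sse, best_k = np.inf, None
    for k in range(1, v.size):  # lower cluster = s[:k]
        if s[k - 1] == s[k]:
            continue  # equal values must share a cluster
        lo, hi = s[:k], s[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_k = sse, k
    upper = np.zeros(v.size, dtype=bool)
    upper[order[best_k:]] = True
    return upper


def brute_median_filter_nonzero(freq: np.ndarray, kernel: int = 3) -> np.ndarray:
    """3x3 median filter excluding zero neighbors, lower-median convention."""
    h, w = freq.shape
    pad = kernel // 2
    out = np.zeros_like(np.asarray(freq, dtype=float))
    for i in range(h):
        for j in range(w):
            if freq[i, j] == 0:
                continue
            vals = []
            for di in range(-pad, pad + 1):
                for dj in range(-pad, pad + 1):
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w and freq[y, x] != 0:
                        vals.append(freq[y, x])
            vals.sort()
            out[i, j] = vals[(len(vals) - 1) // 2] if vals else 0.0
    return out


def brute_opening(mask: np.ndarray, size: int) -> np.ndarray:
    """Mathematical binary opening: union of all fully contained squares."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h - size + 1):
        for j in range(w - size + 1):
            if mask[i : i + size, j : j + size].all():
                out[i : i + size, j : j + size] = True
    return out


def brute_local_maxima(x: np.ndarray) -> list[int]:
    """Strict interior local maxima of a 1-D sequence."""
    return [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1]
    ]


def brute_min_distance_peaks(x: np.ndarray, d: int) -> list[int]:
    """Greedy minimum-distance peak selection, highest first.

    Enumerates strict local maxima, then keeps them in decreasing height
    order, discarding any candidate within ``< d`` samples of an already
    kept peak.  Returned sorted by time.
    """
    candidates = brute_local_maxima(x)
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -x[i]):
        if all(abs(i - j) >= d for j in kept):
            kept.append(i)
    return sorted(kept)


def brute_dominant_frequency(sig: np.ndarray, fs: float, low: float, high: float) -> float:
    """Periodogram argmax over in-band bins of a single 1-D series."""
    t = len(sig)
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(sig))
    band = np.flatnonzero((freqs >= low) & (freqs <= high))
    return float(freqs[band[np.argmax(mag[band])]])


def butterworth_bandpass_gain(f: float, low: float, high: float, order: int = 6) -> float:
    """Analytic squared-magnitude gain of an order-``order`` Butterworth
    band-pass evaluated at frequency ``f`` (single pass).

    The band transform maps the N-pole low-pass prototype (N = order/2) to
    |H(jw)|^2 = 1 / (1 + ((w^2 - w0^2) / (w * B))^(2N)) with w0^2 = wl*wh
    and B = wh - wl (all in rad/s; ratios make Hz equivalent).
    """
    n = order // 2
    w, wl, wh = f, low, high
    x = (w**2 - wl * wh) / (w * (wh - wl))
    return 1.0 / (1.0 + x ** (2 * n))
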