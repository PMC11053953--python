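"""Small NumPy neural networks for the classification harness.

Two trainable backbones share one interface (``fit`` / ``predict``):

* :class:`TinyCNN` — an average-pooling stem followed by three 3 x 3
  convolution blocks (8, 16, 32 filters, ReLU, 2 x 2 max pooling after the
  first two), global average pooling, dropout and a linear head.  Small
  enough to train on a single CPU in seconds yet expressive enough to learn
  spatial amplitude patterns in feature blocks.
* :class:`LinearModel` — flatten plus a linear head; useful as a fast
  baseline and in statistical tests of the training procedure itself.

Training uses class-weighted softmax cross-entropy (weights supplied by the
harness to counter class imbalance), the Adam optimizer, inverted dropout
and an optional per-sample augmentation hook.  All randomness flows through
a single ``numpy`` generator, so runs are reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["TrainConfig", "TinyCNN", "LinearModel", "build_model"]

AugmentFn = Callable[[np.ndarray, np.random.Generator], np.ndarray]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the classification recipe:
    25 epochs, learning rate 0.001, batch size 64, dropout 0.5)."""

    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.5
    weighted_loss: bool = True
    augment: bool = True
    pixel_drop_p: float = 1.0 / 124.0
    # per-block standardization of classifier inputs; off by default (the
    # features are consumed raw, on the gray-level scale)
    normalize_inputs: bool = False


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches with zero 'same' padding."""
    n, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # windows: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    return np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n, h, w, k * k * c
    )


def _col2im(dcols: np.ndarray, shape: tuple[int, ...], k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the image."""
    n, h, w, c = shape
    pad = k // 2
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    d6 = dcols.reshape(n, h, w, k, k, c)
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + h, dj : dj + w, :] += d6[:, :, :, di, dj, :]
    return dxp[:, pad : pad + h, pad : pad + w, :]


def _weighted_softmax_ce(
    logits: np.ndarray, y: np.ndarray, sample_w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(probs[np.arange(n), y] + 1e-12)
    wsum = sample_w.sum()
    loss = float((sample_w * nll).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_w / wsum)[:, None]
    return loss, dlogits


def _avgpool(x: np.ndarray, p: int) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // p, p, w // p, p, c).mean(axis=(2, 4))


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    xc = x[:, :h2, :w2]
    r = xc.reshape(n, h2 // 2, 2, w2 // 2, 2, c)
    out = r.max(axis=(2, 4))
    mask = r == out[:, :, None, :, None, :]
    return out, mask


def _maxpool2_back(dout: np.ndarray, mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    n, h, w, c = shape
    dxc = (mask * dout[:, :, None, :, None, :]).reshape(n, h // 2 * 2, w // 2 * 2, c)
    if dxc.shape[1:3] != (h, w):
        dx = np.zeros(shape)
        dx[:, : dxc.shape[1], : dxc.shape[2]] = dxc
        return dx
    return dxc


class TinyCNN:
    """Three-conv-block CNN with a pooled stem and a linear head."""

    def __init__(
        self,
        input_depth: int,
        n_classes: int = 5,
        input_hw: int = 224,
        channels: tuple[int, int, int] = (8, 16, 32),
        seed: int = 0,
    ):
        self.input_depth = input_depth
        self.n_classes = n_classes
        self.input_hw = input_hw
        self.stem_pool = max(1, input_hw // 28)
        if input_hw % self.stem_pool:
            raise ValueError(f"input size {input_hw} not divisible by stem pool")
        rng = np.random.default_rng(seed)
        c0 = input_depth
        self.params: list[np.ndarray] = []
        self._conv_shapes = []
        for c1 in channels:
            w = rng.normal(0.0, np.sqrt(2.0 / (9 * c0)), size=(9 * c0, c1)).astype(np.float32)
            b = np.zeros(c1, dtype=np.float32)
            self.params += [w, b]
            self._conv_shapes.append((c0, c1))
            c0 = c1
        wd = rng.normal(0.0, np.sqrt(2.0 / c0), size=(c0, n_classes)).astype(np.float32)
        bd = np.zeros(n_classes, dtype=np.float32)
        self.params += [wd, bd]

    # -- forward / backward ------------------------------------------------
    def _forward(
        self, x: np.ndarray, train: bool, dropout: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, dict]:
        cache: dict = {}
        x32 = np.ascontiguousarray(x, dtype=np.float32)
        h = _avgpool(x32, self.stem_pool) if self.stem_pool > 1 else x32
        acts, cols, masks, pmasks, pshapes = [], [], [], [], []
        for li, (c0, c1) in enumerate(self._conv_shapes):
            w, b = self.params[2 * li], self.params[2 * li + 1]
            col = _im2col(h, 3)
            z = col @ w + b
            relu = z > 0
            h = z * relu
            acts.append(h.shape)
            cols.append(col)
            masks.append(relu)
            if li < 2:
                pshapes.append(h.shape)
                h, pm = _maxpool2(h)
                pmasks.append(pm)
        gap_in_shape = h.shape
        feat = h.mean(axis=(1, 2))
        if train and dropout > 0:
            drop = (rng.random(feat.shape) >= dropout) / (1.0 - dropout)
            feat = feat * drop
        else:
            drop = None
        wd, bd = self.params[-2], self.params[-1]
        logits = feat @ wd + bd
        cache.update(
            cols=cols, relu=masks, pmasks=pmasks, pshapes=pshapes,
            gap_in_shape=gap_in_shape, feat=feat, drop=drop, x_shape=x.shape,
        )
        return logits, cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> list[np.ndarray]:
        wd = self.params[-2]
        grads: list[np.ndarray] = [None] * len(self.params)
        grads[-2] = cache["feat"].T @ dlogits
        grads[-1] = dlogits.sum(axis=0)
        dfeat = dlogits @ wd.T
        if cache["drop"] is not None:
            dfeat = dfeat * cache["drop"]
        n, gh, gw, gc = cache["gap_in_shape"]
        dh = np.broadcast_to(dfeat[:, None, None, :], (n, gh, gw, gc)) / (gh * gw)
        for li in range(len(self._conv_shapes) - 1, -1, -1):
            if li < 2:
                dh = _maxpool2_back(dh, cache["pmasks"][li], cache["pshapes"][li])
            dz = dh * cache["relu"][li]
            col = cache["cols"][li]
            nn_, hh, ww, kk = col.shape
            dz2 = dz.reshape(-1, dz.shape[-1])
            grads[2 * li] = col.reshape(-1, kk).T @ dz2
            grads[2 * li + 1] = dz2.sum(axis=0)
            dcol = dz2 @ self.params[2 * li].T
            c_in = self._conv_shapes[li][0]
            prev_hw = (nn_, hh, ww, c_in)
            dh = _col2im(dcol.reshape(nn_, hh, ww, kk), prev_hw, 3)
            if li == 0 and self.stem_pool > 1:
                pass  # stem pool has no parameters; gradient stops here
        return grads

    # -- public interface ----------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        class_weight: np.ndarray | None,
        cfg: TrainConfig,
        rng: np.random.Generator,
        augment_fn: AugmentFn | None = None,
    ) -> list[float]:
        """Train in place; returns the per-epoch mean losses."""
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y)
        n = len(y)
        cw = (
            np.asarray(class_weight, dtype=float)
            if (class_weight is not None and cfg.weighted_loss)
            else np.ones(self.n_classes)
        )
        opt = _Adam(self.params, cfg.learning_rate)
        losses = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = x[idx]
                if cfg.augment and augment_fn is not None:
                    xb = np.stack([augment_fn(b, rng) for b in xb])
                logits, cache = self._forward(xb, True, cfg.dropout, rng)
                loss, dlogits = _weighted_softmax_ce(logits, y[idx], cw[y[idx]])
                grads = self._backward(cache, dlogits)
                opt.step(grads)
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / n)
        return losses

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        rng = np.random.default_rng(0)  # unused at eval (no dropout)
        out = [
            self._forward(x[s : s + batch_size], False, 0.0, rng)[0]
            for s in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_logits(x).argmax(axis=1)


class LinearModel:
    """Flatten + linear head trained with the same loop as the CNN."""

    def __init__(self, input_depth: int, n_classes: int = 5, input_hw: int = 224,
                 seed: int = 0):
        self.n_classes = n_classes
        dim = input_hw * input_hw * input_depth
        rng = np.random.default_rng(seed)
        self.params = [
            rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, n_classes)),
            np.zeros(n_classes),
        ]

    def fit(self, x, y, class_weight, cfg: TrainConfig, rng, augment_fn=None):
        x = np.asarray(x, dtype=np.float32).reshape(len(x), -1)
        y = np.asarray(y)
        cw = (
            np.asarray(class_weight, dtype=float)
            if (class_weight is not None and cfg.weighted_loss)
            else np.ones(self.n_classes)
        )
        opt = _Adam(self.params, cfg.learning_rate)
        losses = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(y))
            epoch_loss = 0.0
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = x[idx] @ self.params[0] + self.params[1]
                loss, dlogits = _weighted_softmax_ce(logits, y[idx], cw[y[idx]])
                opt.step([x[idx].T @ dlogits, dlogits.sum(axis=0)])
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / len(y))
        return losses

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32).reshape(len(x), -1)
        return (x @ self.params[0] + self.params[1]).argmax(axis=1)


def build_model(
    input_depth: int,
    n_classes: int = 5,
    backbone: str = "tiny",
    input_hw: int = 224,
    seed: int = 0,
):
    """Construct a classifier backbone.

    ``tiny`` is the default CNN; ``linear`` is a fast flatten-plus-head
    baseline.  The first layer accepts ``input_hw x input_hw x input_depth``
    blocks (so concatenated multi-feature inputs of depth 10, 15, ... are
    accepted) and the head outputs ``n_classes`` logits.
    """
    if input_depth < 1:
        raise ValueError("input_depth must be >= 1")
    if backbone == "tiny":
        return TinyCNN(input_depth, n_classes, input_hw, seed=seed)
    if backbone == "linear":
        return LinearModel(input_depth, n_classes, input_hw, seed=seed)
    raise ValueError(f"unsupported backbone {backbone!r}; choose 'tiny' or 'linear'")
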