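"""Minimal numpy convolutional network machinery.

Stride-1 convolutions via im2col with explicit backward passes, 2x2 average
pooling for downsampling, and Adam.  Everything is float64 and driven by a
single seeded Generator, so training and inference are bit-reproducible on
the same machine.  Sized for desk-scale models (a few thousand parameters,
a few hundred 64x64 tiles) where this is fast enough without a deep-learning
framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None, pad: int):
    """x (N,C,H,W), W (Co,C,k,k), stride 1 -> (out (N,Co,H',W'), cols)."""
    k = W.shape[-1]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))      # (N,C,H',W',k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    n, ho, wo = cols.shape[:3]
    cols = cols.reshape(n, ho, wo, -1)
    out = cols @ W.reshape(W.shape[0], -1).T
    if b is not None:
        out = out + b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), cols


class Conv2d:
    """Stride-1 2-D convolution with He initialization."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, pad: int | None = None):
        self.k, self.pad = k, (k // 2 if pad is None else pad)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self._cols = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        out, self._cols = _conv_forward(x, self.W, self.b, self.pad)
        return out

    def backward(self, dout):
        n, co, ho, wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        dW = (dflat.T @ cols).reshape(self.W.shape)
        db = dflat.sum(axis=0)
        # dx = conv(dout, W^T flipped), padding k-1-pad
        Wt = np.ascontiguousarray(self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx, _ = _conv_forward(dout, Wt, None, self.k - 1 - self.pad)
        self.grads = [dW, db]
        return dx


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class AvgPool2:
    """2x2 average pooling (inputs must have even spatial dims)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3)
        return up / 4.0


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def bce_with_logits(logits, labels, weights):
    """Weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps))
    total_w = weights.sum()
    if total_w == 0:
        return 0.0, np.zeros_like(logits)
    loss = float((loss * weights).sum() / total_w)
    grad = (p - labels) * weights / total_w
    return loss, grad


def smooth_l1(pred, target, weights):
    """Huber loss (delta=1); returns (loss, dloss/dpred)."""
    d = pred - target
    absd = np.abs(d)
    loss_el = np.where(absd < 1.0, 0.5 * d * d, absd - 0.5)
    total_w = weights.sum()
    if total_w == 0:
        return 0.0, np.zeros_like(pred)
    loss = float((loss_el * weights).sum() / total_w)
    grad = np.clip(d, -1.0, 1.0) * weights / total_w
    return loss, grad
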