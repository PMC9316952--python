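"""Minimal CPU neural-network engine used by the bifocal classifier.

Implements exactly the pieces the two-branch patch classifier needs —
3x3 same-padding convolution (im2col + GEMM), ReLU, 2x2 max-pooling,
global average pooling, dense layers, softmax cross-entropy and SGD with
momentum, weight decay and cosine learning-rate decay. Everything is
float32 numpy; forward/backward passes are deterministic on a single
thread, which is what makes seeded training runs bit-reproducible.

Layout convention: activations are channels-last ``(N, H, W, C)``
float32 arrays (image order, so crops feed in without transposition and
im2col needs no axis shuffling).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "SGD",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3/pad-1 patch matrix: (N,H,W,C) -> (N*H*W, 9*C).

    Column order is (ky, kx, c); assembled with nine block copies, which
    is far cheaper than gathering a 6-D strided view.
    """
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, w, 9, c), dtype=x.dtype)
    k = 0
    for ky in range(3):
        for kx in range(3):
            out[:, :, :, k, :] = xp[:, ky:ky + h, kx:kx + w, :]
            k += 1
    return out.reshape(n * h * w, 9 * c)


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving).

    ``input_grad=False`` (the first layer of a branch) skips the costly
    gradient w.r.t. the input images, which nothing consumes.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad
        # He initialisation for ReLU stacks; weight rows match im2col
        # column order (ky, kx, c_in)
        w = rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), size=(9 * c_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, h, w, c = x.shape
        cols = _im2col3(x)
        y = cols @ self.w.value + self.b.value
        self._cols, self._shape = cols, x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        n, h, w, c = self._shape
        dyf = dy.reshape(-1, self.c_out)
        self.w.grad[...] = self._cols.T @ dyf
        self.b.grad[...] = dyf.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return None
        # input gradient as nine small GEMMs accumulated into a padded
        # buffer (equivalent to convolving dy with the flipped kernels,
        # but avoids materialising a second im2col matrix)
        wk = self.w.value.reshape(3, 3, c, self.c_out)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dy.dtype)
        for ky in range(3):
            for kx in range(3):
                t = dyf @ wk[ky, kx].T
                dxp[:, ky:ky + h, kx:kx + w, :] += t.reshape(n, h, w, c)
        return dxp[:, 1:h + 1, 1:w + 1, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        self._blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)  # view, no copy
        self._y = self._blocks.max(axis=(2, 4))
        self._shape = x.shape
        return self._y

    def backward(self, dy):
        # split the gradient equally among tied maxima so the layer is an
        # exact subgradient (keeps finite-difference checks honest)
        mask = self._blocks == self._y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dy[:, :, None, :, None, :] / counts)
        return dx.reshape(self._shape)


class Flatten(Layer):
    """(N,H,W,C) -> (N, H*W*C); keeps spatial layout in the feature order."""

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(N,H,W,C) -> (N,C) by spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad[...] = self._x.T @ dy
        self.b.grad[...] = dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    """SGD with momentum, L2 weight decay and cosine LR decay.

    The learning rate follows ``lr_min + (lr0 - lr_min) *
    (1 + cos(pi * t / T)) / 2`` over the scheduled number of steps,
    a monotone decay from ``lr0`` to ``lr_min``.
    """

    def __init__(self, params: list[Param], lr: float = 5e-4, momentum: float = 0.9,
                 weight_decay: float = 5e-3, lr_min: float | None = None,
                 total_steps: int | None = None):
        self.params = params
        self.lr0 = lr
        self.lr_min = lr if lr_min is None else lr_min
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.step_count = 0

    @property
    def lr(self) -> float:
        if not self.total_steps or self.total_steps <= 1:
            return self.lr0
        t = min(self.step_count, self.total_steps) / self.total_steps
        return self.lr_min + (self.lr0 - self.lr_min) * 0.5 * (1.0 + np.cos(np.pi * t))

    def step(self):
        lr = self.lr
        for p in self.params:
            g = p.grad + self.weight_decay * p.value
            p.velocity *= self.momentum
            p.velocity -= lr * g
            p.value += p.velocity
        self.step_count += 1
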