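"""Minimal convolutional building blocks with explicit backpropagation.

Only the layers the modified U-net needs are implemented: same-padded
square convolutions (3x3 and the final 1x1), 2x2 stride-2 max pooling,
2x2 stride-2 transposed convolutions, and ReLU.  Arrays are NCHW
``float32`` by default; a ``float64`` mode exists for gradient checking.

Each layer caches what its backward pass needs during a training-mode
forward pass.  Gradients are written (not accumulated) into ``grads`` on
every backward call, so one forward/backward pair per optimizer step.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2x2",
    "MaxPool2",
    "ReLU",
    "Adam",
    "he_uniform",
]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    """He/Kaiming uniform draw, the standard initialization for ReLU nets."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _corr_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded cross-correlation of NCHW input with (Cout, Cin, k, k) kernels."""
    k = w.shape[-1]
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: (N, Cin, H, W, k, k); tensordot collapses (Cin, k, k)
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N, H, W, Cout)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


class Conv2d:
    """k x k same-padded convolution (k odd), with bias."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernels only")
        self.kernel = kernel
        self.w = he_uniform(rng, (cout, cin, kernel, kernel), cin * kernel * kernel, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return _corr_same(x, self.w) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        k, pad = self.kernel, self.kernel // 2
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, Cin, H, W, k, k)
        self.grads[0][...] = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        # dx = same-padded correlation of dy with the flipped, transposed kernel
        w_t = np.ascontiguousarray(self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        self._x = None
        return _corr_same(dy, w_t)


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling), with bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.w = he_uniform(rng, (cin, cout, 2, 2), cin * 4, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        n, _, h, w = x.shape
        cout = self.w.shape[1]
        y = np.einsum("nchw,cokl->nohkwl", x, self.w, optimize=True)
        y = y.reshape(n, cout, 2 * h, 2 * w)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, cout, h2, w2 = dy.shape
        dyr = dy.reshape(n, cout, h2 // 2, 2, w2 // 2, 2)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        self.grads[0][...] = np.einsum("nchw,nohkwl->cokl", x, dyr, optimize=True)
        self._x = None
        return np.einsum("nohkwl,cokl->nchw", dyr, self.w, optimize=True)


class MaxPool2:
    """2x2 max pooling with stride 2."""

    def __init__(self):
        self.params = []
        self.grads = []
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return dx.reshape(n, c, h, w)


class ReLU:
    def __init__(self):
        self.params = []
        self.grads = []
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0)
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs.

    Defaults beta1=0.9, beta2=0.999, eps=1e-8.
    """

    def __init__(self, pairs, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(pairs)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
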