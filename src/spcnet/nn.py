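"""Minimal CPU neural-network layers with explicit forward/backward passes.

Only what the detection network needs: stride-1 "same" 2D convolution
(im2col + BLAS matmul), ReLU, 2x2 max-pooling, fixed bilinear upsampling, a
numerically stable softmax, and Adam. Arrays are (batch, channels, rows,
cols), float64 for reproducibility across BLAS builds. Every layer caches
what its backward pass needs; gradients accumulate into ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "BilinearUp", "softmax", "Adam"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches for a stride-1 same conv."""
    if k == 1:
        b, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1).reshape(b * h * w, c)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    b, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


class Conv2d:
    """Stride-1 convolution with odd kernel size and "same" zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        y = cols @ self.W.reshape(self.c_out, -1).T + self.b
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        b, c, h, w = x_shape
        gm = g.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        dW = (gm.T @ cols).reshape(self.W.shape)
        db = gm.sum(axis=0)
        self.grads["W"] = self.grads.get("W", 0) + dW
        self.grads["b"] = self.grads.get("b", 0) + db
        # input gradient = same-padded conv of g with the flipped, transposed kernel
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Ci, Co, k, k)
        cols_g = _im2col(g, self.k)
        dx = cols_g @ w_flip.reshape(self.c_in, -1).T
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {(h, w)}")
        win = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(b, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        if train:
            self._cache = (idx, x.shape)
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        out = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
        out = out.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(b, c, h, w)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix (n_out x n_in), half-pixel-centre mapping."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    a[np.arange(n_out), lo] += 1 - t
    a[np.arange(n_out), hi] += t
    return a


class BilinearUp:
    """Fixed (non-learned) bilinear upsampling to a target spatial size."""

    _matrices: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw
        self._in_hw = None

    @classmethod
    def _matrix(cls, n_out: int, n_in: int) -> np.ndarray:
        key = (n_out, n_in)
        if key not in cls._matrices:
            cls._matrices[key] = _interp_matrix(n_out, n_in)
        return cls._matrices[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h_in, w_in = x.shape[2:]
        if train:
            self._in_hw = (h_in, w_in)
        if (h_in, w_in) == self.out_hw:
            return x
        ar = self._matrix(self.out_hw[0], h_in)
        ac = self._matrix(self.out_hw[1], w_in)
        return np.einsum("ih,bchw,jw->bcij", ar, x, ac, optimize=True)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h_in, w_in = self._in_hw
        if (h_in, w_in) == self.out_hw:
            return g
        ar = self._matrix(self.out_hw[0], h_in)
        ac = self._matrix(self.out_hw[1], w_in)
        return np.einsum("ih,bcij,jw->bchw", ar, g, ac, optimize=True)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam over a flat dict of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
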