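"""Layers with explicit forward/backward passes, NHWC layout, float32."""

from __future__ import annotations

import numpy as np

# Global compute dtype; float64 is used by the gradient-check tests.
DTYPE = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H+2p, W+2p, C) padded input -> (N*H*W, k*k*C) patch matrix."""
    n, hp, wp, c = x.shape
    h, w = hp - k + 1, wp - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # windows: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, k * k * c)


class Conv2D:
    """Same-padded stride-1 convolution; He-normal initialization."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 name: str = "conv") -> None:
        self.cin, self.cout, self.k = cin, cout, ksize
        std = np.sqrt(2.0 / (ksize * ksize * cin))
        self.W = Param(rng.normal(0.0, std, (ksize * ksize * cin, cout)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = _im2col(xp, self.k)
        out = cols @ self.W.data + self.b.data
        self._cache = (cols, (n, h, w))
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, h, w) = self._cache
        dm = dout.reshape(n * h * w, self.cout)
        self.W.grad += cols.T @ dm
        self.b.grad += dm.sum(axis=0)
        dcols = (dm @ self.W.data.T).reshape(n, h, w, self.k, self.k, self.cin)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm2D:
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE),
                       x.shape, train)
        return (self.gamma.data * xhat + self.beta.data).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, train = self._cache
        axes = (0, 1, 2)
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data
        if not train:
            return (dxhat * inv_std).astype(DTYPE)
        dx = (inv_std / m) * (m * dxhat
                              - dxhat.sum(axis=axes)
                              - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(DTYPE)


class Dense:
    """Fully connected layer, (N, Cin) -> (N, Cout)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "fc") -> None:
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, (cin, cout)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return (dout @ self.W.data.T).astype(DTYPE)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, dout, 0.0).astype(DTYPE)


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    return out, (x, out)


def maxpool2_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    x, out = cache
    n, h, w, c = x.shape
    up = np.repeat(np.repeat(out, 2, axis=1), 2, axis=2)
    mask = (x == up)
    # split gradient evenly among tied maxima so the op stays exact
    cnt = mask.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
    dup = np.repeat(np.repeat(dout / cnt, 2, axis=1), 2, axis=2)
    return np.where(mask, dup, 0.0).astype(DTYPE)


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(DTYPE)


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(1, 2))


def global_avg_pool_backward(dout: np.ndarray, spatial: tuple[int, int]) -> np.ndarray:
    h, w = spatial
    return (np.repeat(np.repeat(dout[:, None, None, :], h, axis=1), w, axis=2)
            / (h * w)).astype(DTYPE)


def softmax(z: np.ndarray) -> np.ndarray:
    """Stable softmax over the last axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=-1, keepdims=True)).astype(DTYPE)


def softmax_backward(dq: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Chain dL/dq through the softmax Jacobian to dL/dz."""
    inner = (dq * q).sum(axis=-1, keepdims=True)
    return (q * (dq - inner)).astype(DTYPE)
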