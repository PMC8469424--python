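"""Minimal feed-forward layer primitives with hand-written backpropagation.

All arrays are float64 numpy.  Each layer caches whatever its backward pass
needs during ``forward`` and therefore must not be reused for two concurrent
forward passes.  Convolutions are cross-correlations (no kernel flip), the
convention used throughout deep-learning frameworks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1d",
    "LeakyReLU",
    "Softmax",
    "Dropout",
    "LayerNorm",
    "BatchNorm1d",
    "AvgPool1d",
    "AdaptiveAvgPool1d",
    "Flatten",
    "Sequential",
    "cross_entropy",
    "im2col",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward caches, backward consumes the cache once."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(B, C, N) -> (B, C, T, kernel) patch tensor, T = (N-kernel)//stride + 1."""
    win = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=-1)
    return win[:, :, ::stride, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "dense") -> None:
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, gout):
        self.W.grad += self._x.T @ gout
        if self.b is not None:
            self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T


class Conv1d(Layer):
    """1-D cross-correlation over (B, C, N) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 name: str = "conv") -> None:
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.W = Param(rng.uniform(-limit, limit, size=(c_out, c_in, kernel)), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b") if bias else None
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._patches: np.ndarray | None = None
        self._n_in: int = 0

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @staticmethod
    def out_length(n: int, kernel: int, stride: int, padding: int) -> int:
        return (n + 2 * padding - kernel) // stride + 1

    def forward(self, x, training=False):
        self._n_in = x.shape[-1]
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        self._patches = im2col(x, self.kernel, self.stride)
        out = np.einsum("bctk,ock->bot", self._patches, self.W.value, optimize=True)
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out

    def backward(self, gout):
        self.W.grad += np.einsum("bctk,bot->ock", self._patches, gout, optimize=True)
        if self.b is not None:
            self.b.grad += gout.sum(axis=(0, 2))
        # grad wrt input: dilate gout by the stride, then full-correlate with
        # the kernel flipped along its tap axis and transposed in channels.
        b, c_out, t = gout.shape
        k, s, p = self.kernel, self.stride, self.padding
        gd = np.zeros((b, c_out, (t - 1) * s + 1))
        gd[:, :, ::s] = gout
        gd = np.pad(gd, ((0, 0), (0, 0), (k - 1, k - 1)))
        w_flip = self.W.value[:, :, ::-1]
        cols = im2col(gd, k, 1)
        gx = np.einsum("botk,ock->bct", cols, w_flip, optimize=True)
        n_pad = self._n_in + 2 * p
        gx = gx[:, :, :n_pad]
        if gx.shape[-1] < n_pad:  # stride > 1 can truncate the tail
            gx = np.pad(gx, ((0, 0), (0, 0), (0, n_pad - gx.shape[-1])))
        if p:
            gx = gx[:, :, p:-p]
        return gx


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        self.slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class Softmax(Layer):
    """Row-wise softmax over the last axis."""

    def __init__(self) -> None:
        self._p: np.ndarray | None = None

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, gout):
        p = self._p
        return p * (gout - (gout * p).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class LayerNorm(Layer):
    """Per-sample normalization over (C, T) with a per-channel affine map."""

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "ln") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value[None, :, None] + self.beta.value[None, :, None]

    def backward(self, gout):
        xhat, inv = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2))
        self.beta.grad += gout.sum(axis=(0, 2))
        g = gout * self.gamma.value[None, :, None]
        m = xhat.shape[1] * xhat.shape[2]
        gsum = g.sum(axis=(1, 2), keepdims=True)
        gxsum = (g * xhat).sum(axis=(1, 2), keepdims=True)
        return inv * (g - gsum / m - xhat * gxsum / m)


class BatchNorm1d(Layer):
    """Batch normalization over (B, F) feature matrices."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(n_features), f"{name}.gamma")
        self.beta = Param(np.zeros(n_features), f"{name}.beta")
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape[0])
        return xhat * self.gamma.value + self.beta.value

    def backward(self, gout):
        xhat, inv, training, n = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=0)
        self.beta.grad += gout.sum(axis=0)
        g = gout * self.gamma.value
        if not training:
            return g * inv
        return inv / n * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))


class AvgPool1d(Layer):
    """Window-2 style average pooling with ceil semantics.

    Odd-length inputs are padded by repeating the final sample so the output
    length is ceil(N / window); this keeps pooled residual branches aligned
    with stride-``window`` convolutions using symmetric padding.
    """

    def __init__(self, window: int = 2) -> None:
        self.window = window
        self._n_in = 0

    def forward(self, x, training=False):
        w = self.window
        n = x.shape[-1]
        self._n_in = n
        pad = (-n) % w
        if pad:
            x = np.concatenate([x, np.repeat(x[:, :, -1:], pad, axis=-1)], axis=-1)
        return x.reshape(*x.shape[:-1], -1, w).mean(axis=-1)

    def backward(self, gout):
        w = self.window
        gx = np.repeat(gout, w, axis=-1) / w
        n = self._n_in
        if gx.shape[-1] > n:  # fold the padded (repeated-sample) columns back
            extra = gx[:, :, n:].sum(axis=-1)
            gx = gx[:, :, :n].copy()
            gx[:, :, -1] += extra
        return gx


class AdaptiveAvgPool1d(Layer):
    """Average pooling to a fixed output length with torch-style bins."""

    def __init__(self, t_out: int) -> None:
        self.t_out = t_out
        self._bins: list[tuple[int, int]] = []
        self._n_in = 0

    def _edges(self, n: int) -> list[tuple[int, int]]:
        t = self.t_out
        return [((i * n) // t, -(-((i + 1) * n) // t)) for i in range(t)]

    def forward(self, x, training=False):
        n = x.shape[-1]
        self._n_in = n
        self._bins = self._edges(n)
        out = np.empty(x.shape[:-1] + (self.t_out,))
        for i, (lo, hi) in enumerate(self._bins):
            out[..., i] = x[..., lo:hi].mean(axis=-1)
        return out

    def backward(self, gout):
        gx = np.zeros(gout.shape[:-1] + (self._n_in,))
        for i, (lo, hi) in enumerate(self._bins):
            gx[..., lo:hi] += gout[..., i : i + 1] / (hi - lo)
        return gx


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of class-probability rows and its gradient wrt probs."""
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), y], 1e-12, None)
    loss = float(-np.log(p).mean())
    gprobs = np.zeros_like(probs)
    gprobs[np.arange(n), y] = -1.0 / (n * p)
    return loss, gprobs
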