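"""Minimal neural-network core: layers with explicit forward/backward.

The multitask network operates on grayscale sensor images of shape
(T, C): T time samples by C heterogeneous channels. Convolutions slide
along the time axis only (kernel k x 1), preserving the channel axis, so
internal activations are (batch, time, channel, feature) float32 arrays.

Each layer caches what its backward pass needs; a network is a DAG of these
layers driven by :class:`metspecs.model.MultitaskNet`. Optimisation is Adam
with a step-decayed learning rate.
"""
from __future__ import annotations

import numpy as np

from .errors import ConfigError

_EPS_BN = 1e-5


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer; subclasses implement forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvTime(Layer):
    """Valid convolution along the time axis with a (k, 1) kernel.

    Input (B, T, C, F_in) -> output (B, T - k + 1, C, F_out); every channel
    column shares the same kernels.
    """

    def __init__(self, f_in: int, f_out: int, k: int, rng: np.random.Generator):
        if k < 1:
            raise ConfigError("kernel size must be >= 1")
        std = np.sqrt(2.0 / (k * f_in))
        self.k = k
        self.W = Param(rng.normal(0.0, std, size=(k, f_in, f_out)))
        self.b = Param(np.zeros(f_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        B, T, C, F = x.shape
        To = T - self.k + 1
        if To < 1:
            raise ConfigError(
                f"time extent {T} shorter than kernel {self.k}; "
                "reduce blocks/pooling for this input size"
            )
        y = np.zeros((B, To, C, self.W.value.shape[2]), dtype=np.float32)
        for dt in range(self.k):
            y += np.einsum(
                "btcf,fo->btco", x[:, dt : dt + To], self.W.value[dt],
                optimize=True,
            )
        return y + self.b.value

    def backward(self, dy):
        x = self._x
        To = dy.shape[1]
        dx = np.zeros_like(x)
        for dt in range(self.k):
            self.W.grad[dt] += np.einsum(
                "btcf,btco->fo", x[:, dt : dt + To], dy, optimize=True
            )
            dx[:, dt : dt + To] += np.einsum(
                "btco,fo->btcf", dy, self.W.value[dt], optimize=True
            )
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPoolTime(Layer):
    """Non-overlapping average pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ConfigError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x, train, rng):
        B, T, C, F = x.shape
        To = T // self.pool
        if To < 1:
            raise ConfigError(f"time extent {T} shorter than pool {self.pool}")
        self._in_shape = x.shape
        xt = x[:, : To * self.pool].reshape(B, To, self.pool, C, F)
        return xt.mean(axis=2)

    def backward(self, dy):
        B, T, C, F = self._in_shape
        To = dy.shape[1]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : To * self.pool] = np.repeat(
            dy / self.pool, self.pool, axis=1
        ).reshape(B, To * self.pool, C, F)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over the feature axis (statistics over B, T, C)."""

    def __init__(self, f: int, momentum: float = 0.1):
        self.gamma = Param(np.ones(f))
        self.beta = Param(np.zeros(f))
        self.momentum = momentum
        self.running_mean = np.zeros(f, dtype=np.float32)
        self.running_var = np.ones(f, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _EPS_BN).astype(np.float32)
        self._xhat = ((x - mean) / self._std).astype(np.float32)
        self._train = train
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        xhat, std, n = self._xhat, self._std, self._n
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self._train:
            return dy * self.gamma.value / std
        dxhat = dy * self.gamma.value
        return (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) / std


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class TimePoolFlatten(Layer):
    """Global average over the time axis, then flatten channel x feature.

    Makes the downstream head invariant to where in the window a movement
    pattern occurs — the head sees how strongly each convolutional feature
    responds, not at which phase.
    """

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.mean(axis=1).reshape(x.shape[0], -1)

    def backward(self, dy):
        B, T = self._in_shape[:2]
        dy = dy.reshape((B, 1) + self._in_shape[2:]) / T
        return np.broadcast_to(dy, self._in_shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class Adam:
    """Adam over an explicit parameter list; slots keyed by identity."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
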