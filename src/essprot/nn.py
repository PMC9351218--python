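"""Minimal trainable layer library (NumPy, manual backprop).

Implements exactly the layers the classifier needs — dense, 1-D convolution
with same-padding, batch normalization, max pooling, global max pooling —
each as a class with ``forward(x, train)`` / ``backward(dout)`` and exposed
parameter/gradient lists, plus an RMSprop optimizer.  Also exports the
functional forward primitives (``conv1d_forward``, ``batch_norm_forward``,
``dense_forward``) that the feature modules use and the tests oracle-check.

Conventions: batched inputs are ``(batch, time, channels)`` for temporal
layers and ``(batch, features)`` for dense layers; ReLU is the only hidden
activation; weights use Glorot-uniform initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv1d_forward",
    "batch_norm_forward",
    "dense_forward",
    "relu",
    "sigmoid",
    "Dense",
    "Conv1D",
    "BatchNorm",
    "MaxPool1D",
    "GlobalMaxPool",
    "RMSprop",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# Functional forward primitives
# ---------------------------------------------------------------------------

def conv1d_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str | None = "relu",
) -> np.ndarray:
    """Same-padded 1-D cross-correlation over the time axis.

    ``x`` is ``(time, in_channels)`` or ``(batch, time, in_channels)``;
    ``kernels`` is ``(k, in_channels, filters)`` with odd ``k``; output
    channel ``j`` is ``b_j + sum_c W[:, c, j] * x[:, c]``, optionally ReLU'd.
    """
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    k, cin, _ = kernels.shape
    if k % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    if x.shape[2] != cin:
        raise ValueError(f"input has {x.shape[2]} channels, kernels expect {cin}")
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    T = x.shape[1]
    cols = np.stack([xp[:, i : i + T, :] for i in range(k)], axis=2)  # (B,T,k,cin)
    z = np.einsum("btkc,kcf->btf", cols, kernels) + biases
    if activation == "relu":
        z = relu(z)
    elif activation is not None:
        raise ValueError(f"unknown activation {activation!r}")
    return z[0] if squeeze else z


def batch_norm_forward(
    batch: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    eps: float = 1e-3,
    mode: str = "train",
    running_mean: np.ndarray | None = None,
    running_var: np.ndarray | None = None,
    momentum: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch normalization over all axes except the last (feature) axis.

    Train mode standardizes with batch statistics and updates the running
    (inference) statistics with exponential momentum; infer mode uses the
    running statistics unchanged.  Returns ``(y, running_mean, running_var)``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    axes = tuple(range(batch.ndim - 1))
    nfeat = batch.shape[-1]
    if running_mean is None:
        running_mean = np.zeros(nfeat)
    if running_var is None:
        running_var = np.ones(nfeat)
    if mode == "train":
        count = int(np.prod([batch.shape[a] for a in axes])) if axes else 1
        if count < 2:
            raise ValueError("batch normalization in train mode needs batch size >= 2")
        mu = batch.mean(axis=axes)
        var = batch.var(axis=axes)
        running_mean = momentum * running_mean + (1.0 - momentum) * mu
        running_var = momentum * running_var + (1.0 - momentum) * var
    elif mode == "infer":
        mu, var = running_mean, running_var
    else:
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    y = gamma * (batch - mu) / np.sqrt(var + eps) + beta
    return y, running_mean, running_var


def dense_forward(
    x: np.ndarray, weights: np.ndarray, bias: np.ndarray, activation: str | None = "relu"
) -> np.ndarray:
    """Fully connected layer ``y = f(x @ W + b)``."""
    z = x @ weights + bias
    if activation == "relu":
        return relu(z)
    if activation == "sigmoid":
        return sigmoid(z)
    if activation is None:
        return z
    raise ValueError(f"unknown activation {activation!r}")


# ---------------------------------------------------------------------------
# Trainable layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, activation: str | None, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        self._z = x @ self.W + self.b
        if self.activation == "relu":
            return relu(self._z)
        return self._z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * (self._z > 0) if self.activation == "relu" else dout
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T


class Conv1D:
    """Same-padded temporal convolution with ReLU; input ``(B, T, Cin)``."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        self.W = _glorot(rng, (kernel, c_in, filters), kernel * c_in, kernel * filters)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.W.shape[0]
        pad = k // 2
        T = x.shape[1]
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._cols = np.stack([xp[:, i : i + T, :] for i in range(k)], axis=2)
        self._z = np.einsum("btkc,kcf->btf", self._cols, self.W) + self.b
        self._T = T
        return relu(self._z)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * (self._z > 0)
        self.dW[...] = np.einsum("btkc,btf->kcf", self._cols, dz)
        self.db[...] = dz.sum(axis=(0, 1))
        dcols = np.einsum("btf,kcf->btkc", dz, self.W)
        k = self.W.shape[0]
        pad = k // 2
        B, T = dz.shape[0], self._T
        dxp = np.zeros((B, T + 2 * pad, self.W.shape[1]))
        for i in range(k):
            dxp[:, i : i + T, :] += dcols[:, :, i, :]
        return dxp[:, pad : pad + T, :]


class BatchNorm:
    """Normalizes over all axes but the last; trainable scale/shift."""

    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(n_feat)
        self.beta = np.zeros(n_feat)
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            count = int(np.prod([x.shape[a] for a in axes]))
            if count < 2:
                raise ValueError("batch normalization in train mode needs batch size >= 2")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._count = count
        else:
            mu, var = self.running_mean, self.running_var
        self._train = train
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._train:
            return dxhat * self._istd
        n = self._count
        return (
            self._istd
            / n
            * (n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )


class MaxPool1D:
    """Non-overlapping temporal max pooling; drops a trailing odd frame."""

    def __init__(self, pool: int = 2):
        self.pool = pool
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        n = T // self.pool
        self._in_shape = x.shape
        windows = x[:, : n * self.pool, :].reshape(B, n, self.pool, C)
        self._argmax = windows.argmax(axis=2)
        return windows.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, n, C = dout.shape
        dx = np.zeros(self._in_shape)
        dwin = dx[:, : n * self.pool, :].reshape(B, n, self.pool, C)
        bi, ni, ci = np.ogrid[:B, :n, :C]
        dwin[bi, ni, self._argmax, ci] = dout
        return dx


class GlobalMaxPool:
    """Max over the time axis: ``(B, T, C) -> (B, C)``."""

    def __init__(self):
        self.params: list = []
        self.grads: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        self._argmax = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        dx = np.zeros(self._in_shape)
        bi, ci = np.ogrid[:B, :C]
        dx[bi, self._argmax, ci] = dout
        return dx


class RMSprop:
    """RMSprop with Keras-style defaults (rho=0.9, eps=1e-7, no momentum)."""

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            c = self._cache.get(i)
            if c is None:
                c = self._cache[i] = np.zeros_like(p)
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
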