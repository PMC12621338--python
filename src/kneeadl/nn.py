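"""Minimal numpy neural-network primitives with explicit backprop.

No deep-learning framework is assumed in the runtime environment, so
the layers needed by the dual-branch classifier (dense, 2-D valid
convolution, 2x2 max pooling, inverted dropout, multi-layer LSTM) are
implemented directly on numpy arrays, together with the Adam update
rule.  float32 by default for speed; float64 is available for
numerical gradient checks.

All randomness (initialization, dropout masks, batch shuffling) flows
through explicitly passed ``numpy.random.Generator`` instances, which
makes whole training runs bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    a = rng.normal(size=shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q *= np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    return q[: shape[0], : shape[1]].astype(dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis, with optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, name: str = "dense",
                 dtype=np.float32):
        self.W = Param(f"{name}.W",
                       glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype))
        self.b = Param(f"{name}.b", np.zeros(n_out, dtype=dtype))
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        self._x2d = x.reshape(-1, x.shape[-1])
        z = self._x2d @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0)
        return z.reshape(*x.shape[:-1], self.W.value.shape[1])

    def backward(self, grad):
        g2d = grad.reshape(-1, grad.shape[-1]).astype(self.W.value.dtype)
        if self.activation == "relu":
            g2d = g2d * self._mask
        self.W.grad += self._x2d.T @ g2d
        self.b.grad += g2d.sum(axis=0)
        gx = g2d @ self.W.value.T
        return gx.reshape(self._x_shape)


class Conv2DValid(Layer):
    """Valid 2-D convolution (NHWC), square kernel, ReLU, via im2col."""

    def __init__(self, c_in: int, n_filters: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv",
                 dtype=np.float32):
        fan_in = kernel * kernel * c_in
        self.kernel = kernel
        self.W = Param(f"{name}.W",
                       glorot_uniform(rng, (fan_in, n_filters),
                                      fan_in, n_filters, dtype))
        self.b = Param(f"{name}.b", np.zeros(n_filters, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        k = self.kernel
        patches = sliding_window_view(x, (k, k), axis=(1, 2))  # n,h-k+1,w-k+1,c,k,k
        patches = patches.transpose(0, 1, 2, 4, 5, 3)          # ...,k,k,c
        self._oh, self._ow = h - k + 1, w - k + 1
        self._cols = np.ascontiguousarray(
            patches.reshape(n * self._oh * self._ow, k * k * c))
        self._in_shape = x.shape
        z = self._cols @ self.W.value + self.b.value
        self._mask = z > 0
        z = np.where(self._mask, z, 0)
        return z.reshape(n, self._oh, self._ow, -1)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        k = self.kernel
        g2d = grad.reshape(-1, grad.shape[-1]).astype(self.W.value.dtype)
        g2d = g2d * self._mask
        self.W.grad += self._cols.T @ g2d
        self.b.grad += g2d.sum(axis=0)
        gcols = (g2d @ self.W.value.T).reshape(n, self._oh, self._ow, k, k, c)
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        for di in range(k):
            for dj in range(k):
                gx[:, di:di + self._oh, dj:dj + self._ow, :] += gcols[:, :, :, di, dj, :]
        return gx


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling (NHWC); odd trailing rows dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False, rng=None):
        s = self.size
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        self._in_shape = x.shape
        xv = x[:, :oh * s, :ow * s, :].reshape(n, oh, s, ow, s, c)
        out = xv.max(axis=(2, 4))
        self._argmask = xv == out[:, :, None, :, None, :]
        return out

    def backward(self, grad):
        s = self.size
        n, h, w, c = self._in_shape
        oh, ow = h // s, w // s
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        spread = self._argmask * grad[:, :, None, :, None, :]
        # ties (rare with float inputs) split gradient across maxima
        counts = self._argmask.sum(axis=(2, 4), keepdims=True)
        spread = spread / counts
        gx[:, :oh * s, :ow * s, :] = spread.reshape(n, oh * s, ow * s, c)
        return gx


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class LSTM(Layer):
    """Single LSTM layer over (N, T, D) input.

    Gate order i, f, g, o.  Forget-gate bias initialized to 1.
    ``return_sequences`` controls whether the full hidden sequence
    (N, T, H) or only the last hidden state (N, H) is returned.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False, name: str = "lstm",
                 dtype=np.float32):
        self.units = units
        self.return_sequences = return_sequences
        self.Wx = Param(f"{name}.Wx",
                        glorot_uniform(rng, (n_in, 4 * units), n_in, units, dtype))
        self.Wh = Param(f"{name}.Wh", np.concatenate(
            [orthogonal(rng, (units, units), dtype) for _ in range(4)], axis=1))
        b = np.zeros(4 * units, dtype=dtype)
        b[units:2 * units] = 1.0  # forget gate
        self.b = Param(f"{name}.b", b)

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False, rng=None):
        n, t, _ = x.shape
        h_units = self.units
        dtype = self.Wx.value.dtype
        self._x = x
        # precompute input projections for all timesteps at once
        zx = x.reshape(n * t, -1) @ self.Wx.value
        zx = zx.reshape(n, t, 4 * h_units)
        h = np.zeros((n, h_units), dtype=dtype)
        c = np.zeros((n, h_units), dtype=dtype)
        self._cache = []
        hs = np.empty((n, t, h_units), dtype=dtype)
        for step in range(t):
            z = zx[:, step, :] + h @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :h_units])
            f = sigmoid(z[:, h_units:2 * h_units])
            g = np.tanh(z[:, 2 * h_units:3 * h_units])
            o = sigmoid(z[:, 3 * h_units:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, step, :] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad):
        n, t, _ = self._x.shape
        h_units = self.units
        dtype = self.Wx.value.dtype
        if self.return_sequences:
            dhs = grad.astype(dtype)
        else:
            dhs = np.zeros((n, t, h_units), dtype=dtype)
            dhs[:, -1, :] = grad
        dh_next = np.zeros((n, h_units), dtype=dtype)
        dc_next = np.zeros((n, h_units), dtype=dtype)
        dzx = np.empty((n, t, 4 * h_units), dtype=dtype)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
            dzx[:, step, :] = dz
        x2d = self._x.reshape(n * t, -1)
        dz2d = dzx.reshape(n * t, -1)
        self.Wx.grad += x2d.T @ dz2d
        return (dz2d @ self.Wx.value.T).reshape(self._x.shape)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    """Adam with standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
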