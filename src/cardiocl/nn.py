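"""Minimal NumPy neural-network layers with manual backpropagation.

The training stack (1D convolutions, batch norm, pooling, linear layers,
Adam) is implemented directly on NumPy arrays because no autodiff framework
is assumed at runtime.  Every layer caches what its backward pass needs
during ``forward`` and releases it on the next call.  All parameters are
float32; layer input/output layout is ``(batch, channels, length)`` for
convolutional layers and ``(batch, features)`` for dense layers.

Correctness of every backward pass is pinned by finite-difference gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv1d(Layer):
    """1D convolution, stride 1, symmetric zero padding (length preserving
    when ``2 * pad == kernel - 1``)."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, pad: int = 1, *,
                 rng: np.random.Generator, name: str = "conv"):
        self.cin, self.cout, self.kernel, self.pad = cin, cout, kernel, pad
        self.w = Param(f"{name}.w", he_init(rng, (cout, cin, kernel), cin * kernel))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))
        self._cols = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        Lout = L + 2 * self.pad - self.kernel + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        # win: (B, C, Lout, K) -> cols (B*Lout, C*K)
        cols = win.transpose(0, 2, 1, 3).reshape(B * Lout, C * self.kernel)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wmat = self.w.value.reshape(self.cout, C * self.kernel)
        y = cols @ wmat.T + self.b.value
        self._cols = cols if train else None
        self._in_len = L
        return y.reshape(B, Lout, self.cout).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Co, Lout = dy.shape
        L, K, pad = self._in_len, self.kernel, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1).reshape(B * Lout, Co), dtype=np.float32)
        self.w.grad += (dyf.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        wmat = self.w.value.reshape(Co, self.cin * K)
        dcols = (dyf @ wmat).reshape(B, Lout, self.cin, K)
        dxp = np.zeros((B, self.cin, L + 2 * pad), dtype=np.float32)
        for k in range(K):
            dxp[:, :, k:k + Lout] += dcols[:, :, :, k].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pad:pad + L] if pad else dxp

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm1d(Layer):
    def __init__(self, c: int, *, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        if train:
            self._cache = (xhat, inv)
        return (self.gamma.value[:, None] * xhat + self.beta.value[:, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[:, None] * inv[:, None]
        return (g * (dy - dbeta[:, None] / n - xhat * dgamma[:, None] / n)).astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling; input length must be divisible by size."""

    def __init__(self, size: int = 2):
        self.size = size
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if L % self.size:
            raise ValueError(f"length {L} not divisible by pool size {self.size}")
        xr = x.reshape(B, C, L // self.size, self.size)
        arg = xr.argmax(axis=3)
        y = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
        if train:
            self._arg = arg
            self._shape = (B, C, L)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        dxr = np.zeros((B, C, L // self.size, self.size), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        self._arg = None
        return dxr.reshape(B, C, L)


class GlobalAvgPool1d(Layer):
    """(B, C, L) -> (B, C) by averaging over time."""

    def __init__(self):
        self._len = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (np.repeat(dy[:, :, None], self._len, axis=2) / self._len).astype(np.float32)


class Linear(Layer):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator, name: str = "fc"):
        self.w = Param(f"{name}.w", he_init(rng, (din, dout), din))
        self.b = Param(f"{name}.b", np.zeros(dout, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices of shape (B,).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    grad = p.copy()
    grad[np.arange(B), labels] -= 1.0
    return float(nll.mean()), (grad / B).astype(np.float32)
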