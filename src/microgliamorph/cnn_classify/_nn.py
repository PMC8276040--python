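"""Minimal NumPy neural-network backend (channels-last, float32).

No deep-learning framework is assumed at runtime, so the few layer types the
phenotype classifier needs are implemented here directly: 3x3 same-padding
convolution, ReLU, batch normalization, 2x2 max pooling, dense layers,
inverted dropout and a softmax cross-entropy head, optimized with Adam.
Convolutions are evaluated as nine BLAS matmuls (one per kernel offset)
rather than via an explicit im2col buffer.

Activations are ``(N, H, W, C)`` arrays.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer; stateless layers override forward/backward only."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; gradients are same-shape buffers."""
        return []

    def state(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * in_ch)).astype(F32)
        self.w = rng.standard_normal((3, 3, in_ch, out_ch), dtype=F32) * scale
        self.b = np.zeros(out_ch, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x, train):
        n, h, w, _ = x.shape
        xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.zeros((n, h, w, self.w.shape[3]), dtype=F32)
        for dy in range(3):
            for dx in range(3):
                out += xpad[:, dy : dy + h, dx : dx + w, :] @ self.w[dy, dx]
        out += self.b
        if train:
            self._xpad = xpad
        return out

    def backward(self, grad):
        xpad = self._xpad
        n, h, w, _ = grad.shape
        self.db[:] = grad.sum(axis=(0, 1, 2))
        dxpad = np.zeros_like(xpad)
        gflat = grad.reshape(-1, grad.shape[3])
        for dy in range(3):
            for dx in range(3):
                patch = xpad[:, dy : dy + h, dx : dx + w, :]
                self.dw[dy, dx] = patch.reshape(-1, patch.shape[3]).T @ gflat
                dxpad[:, dy : dy + h, dx : dx + w, :] += grad @ self.w[dy, dx].T
        self._xpad = None
        return dxpad[:, 1:-1, 1:-1, :]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state(self):
        return {"w": self.w, "b": self.b}

    def load_state(self, state):
        self.w[:] = state["w"]
        self.b[:] = state["b"]


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization (over N, H, W for 4D inputs)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat.astype(F32), inv_std.astype(F32))
        return (xhat * self.gamma + self.beta).astype(F32)

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = self._axes(grad)
        m = float(np.prod([grad.shape[a] for a in axes]))
        self.dgamma[:] = (grad * xhat).sum(axis=axes)
        self.dbeta[:] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        self._cache = None
        return dx.astype(F32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return {
            "gamma": self.gamma, "beta": self.beta,
            "running_mean": self.running_mean, "running_var": self.running_var,
        }

    def load_state(self, state):
        self.gamma[:] = state["gamma"]
        self.beta[:] = state["beta"]
        self.running_mean[:] = state["running_mean"]
        self.running_var[:] = state["running_var"]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        win = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dwin, self._idx[..., None], grad[..., None], axis=-1)
        dx = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features).astype(F32)
        self.w = rng.standard_normal((in_features, out_features), dtype=F32) * scale
        self.b = np.zeros(out_features, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state(self):
        return {"w": self.w, "b": self.b}

    def load_state(self, state):
        self.w[:] = state["w"]
        self.b[:] = state["b"]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state(self) -> list[dict]:
        return [layer.state() for layer in self.layers]

    def load_state(self, states: list[dict]) -> None:
        for layer, st in zip(self.layers, states):
            layer.load_state(st)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean loss and gradient w.r.t. logits for integer labels."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(F32)


class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
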