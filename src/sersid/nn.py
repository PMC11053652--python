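"""A compact NumPy engine for 1-D convolutional networks.

Implements exactly the layer set the spectral classifier needs — 1-D "same"
convolution, batch normalization (feature-map and dense variants), ReLU, max
pooling, dense layers, inverted dropout, and a fused softmax/cross-entropy
head — with hand-written backward passes and SGD with momentum and weight
decay.  All arithmetic is float32; convolutions are expressed as one matrix
product per kernel tap so the heavy lifting stays inside BLAS.

Shapes: feature maps are ``(N, L, C)`` (channels last — keeps the per-tap
matrix products contiguous for BLAS); dense activations are ``(N, F)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm",
    "ReLU",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "SGD",
    "softmax",
    "cross_entropy_grad",
]

F32 = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(F32)


class Layer:
    params: list  # list of [value, grad, velocity] triples

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _param(self, value: np.ndarray) -> list:
        p = [value.astype(F32), np.zeros_like(value, dtype=F32), np.zeros_like(value, dtype=F32)]
        self.params.append(p)
        return p


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding, stride 1, channels-last maps."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel width must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = self._param(rng.normal(0.0, scale, (k, c_in, c_out)))
        self.b = self._param(np.zeros(c_out))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, L, c = x.shape
        p = self.k // 2
        xp = np.zeros((n, L + 2 * p, c), dtype=F32)
        xp[:, p : p + L, :] = x
        self._xp, self._L = xp, L
        w = self.params[0][0]
        y = np.empty((n, L, self.c_out), dtype=F32)
        y[:] = self.params[1][0]
        for j in range(self.k):
            y += xp[:, j : j + L, :] @ w[j]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        w = self.params[0][0]
        p = self.k // 2
        dw = self.params[0][1]
        dxp = np.zeros_like(xp)
        gf = grad.reshape(-1, self.c_out)
        for j in range(self.k):
            dw[j] = xp[:, j : j + L, :].reshape(-1, self.c_in).T @ gf
            dxp[:, j : j + L, :] += grad @ w[j].T
        self.params[1][1][:] = grad.sum(axis=(0, 1))
        return dxp[:, p : p + L, :]


class BatchNorm(Layer):
    """Batch normalization over (N, L) per channel for maps, over N for dense input."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = self._param(np.ones(n_features))
        self.beta = self._param(np.zeros(n_features))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(n_features, dtype=F32)
        self.run_var = np.ones(n_features, dtype=F32)

    def _axes(self, x: np.ndarray):
        return (0, 1) if x.ndim == 3 else (0,)

    def _shape(self, x: np.ndarray):
        return (1, 1, -1) if x.ndim == 3 else (1, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if train:
            cnt = x.size // x.shape[-1]
            mean = x.mean(axis=axes)
            if x.ndim == 3:
                m2 = np.einsum("nlc,nlc->c", x, x, optimize=True) / cnt
            else:
                m2 = np.einsum("nf,nf->f", x, x, optimize=True) / cnt
            var = np.maximum(m2 - mean * mean, 0.0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = x - mean.reshape(shp).astype(F32)
        xhat *= inv.reshape(shp)
        if train:
            self._xhat, self._inv = xhat, inv
        y = xhat * self.gamma[0].reshape(shp)
        y += self.beta[0].reshape(shp)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(grad), self._shape(grad)
        xhat, inv = self._xhat, self._inv
        if grad.ndim == 3:
            self.params[0][1][:] = np.einsum("nlc,nlc->c", grad, xhat, optimize=True)
        else:
            self.params[0][1][:] = np.einsum("nf,nf->f", grad, xhat, optimize=True)
        self.params[1][1][:] = grad.sum(axis=axes)
        cnt = grad.size // grad.shape[-1]
        dxhat = grad * self.gamma[0].reshape(shp)
        dx = dxhat
        dx -= (self.params[1][1] * self.gamma[0] / cnt).reshape(shp)
        xhat *= (self.params[0][1] / cnt).reshape(shp)
        dx -= xhat
        dx *= inv.reshape(shp)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        np.multiply(grad, self._mask, out=grad)
        return grad


class MaxPool1d(Layer):
    """Max pooling along the length axis, window 2, stride 2; odd tail dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, L, c = x.shape
        L2 = L // 2
        if L2 < 1:
            raise ValueError("input too short to pool")
        xw = x[:, : 2 * L2, :].reshape(n, L2, 2, c)
        self._arg = xw.argmax(axis=2)
        self._in_shape = x.shape
        return xw.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, L, c = self._in_shape
        L2 = L // 2
        dx = np.zeros((n, L, c), dtype=F32)
        dxw = dx[:, : 2 * L2, :].reshape(n, L2, 2, c)
        np.put_along_axis(dxw, self._arg[:, :, None, :], grad[:, :, None, :].astype(F32), axis=2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = self._param(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = self._param(np.zeros(n_out))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return (x @ self.params[0][0] + self.params[1][0]).astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.params[0][1][:] = self._x.T @ grad
        self.params[1][1][:] = grad.sum(axis=0)
        return (grad @ self.params[0][0].T).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Network:
    """A plain layer sequence ending in logits (softmax applied by the caller)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p[0].copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[0][:] = w

    def n_parameters(self) -> int:
        return sum(p[0].size for p in self.params)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params: list, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        self.params, self.lr, self.momentum, self.wd = params, lr, momentum, weight_decay

    def step(self) -> None:
        for value, grad, vel in self.params:
            g = grad + self.wd * value
            vel *= self.momentum
            vel -= self.lr * g
            value += vel
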