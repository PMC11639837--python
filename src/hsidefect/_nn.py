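"""Minimal deterministic neural-network primitives.

Small NumPy layer library with explicit forward/backward passes, used by the
1-D spectral classifier and the 2-D detectors.  Everything is seeded through a
``numpy.random.Generator`` and runs single-threaded, so training is
bit-reproducible on CPU.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Array = np.ndarray


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> Array:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Layer:
    """Base layer: ``params``/``grads`` are parallel tuples of arrays."""

    params: tuple = ()
    grads: tuple = ()

    def forward(self, x: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = (self.W, self.b)
        self.grads = (self.dW, self.db)

    def forward(self, x: Array) -> Array:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: Array) -> Array:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x: Array) -> Array:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: Array) -> Array:
        return np.where(self._mask, grad, 0.0)


class Conv1D(Layer):
    """'same' 1-D convolution, stride 1, odd kernel. Input (N, C, L)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.W = he_init(rng, (c_out, c_in, k), c_in * k)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = (self.W, self.b)
        self.grads = (self.dW, self.db)

    def forward(self, x: Array) -> Array:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
        self._cols = cols
        self._L = x.shape[2]
        y = np.einsum("nclk,ock->nol", cols, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, grad: Array) -> Array:
        k, p, L = self.k, self.k // 2, self._L
        self.dW[...] = np.einsum("nol,nclk->ock", grad, self._cols, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2))
        t = np.einsum("nol,ock->nckl", grad, self.W, optimize=True)
        dxp = np.zeros((grad.shape[0], self.W.shape[1], L + 2 * p))
        for kk in range(k):
            dxp[:, :, kk : kk + L] += t[:, :, kk, :]
        return dxp[:, :, p : p + L]


class MaxPool1D(Layer):
    """Non-overlapping size-2 max pooling; odd tail is dropped."""

    def forward(self, x: Array) -> Array:
        N, C, L = x.shape
        L2 = L // 2
        self._shape = x.shape
        xr = x[:, :, : 2 * L2].reshape(N, C, L2, 2)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, grad: Array) -> Array:
        N, C, L = self._shape
        L2 = L // 2
        dxr = np.zeros((N, C, L2, 2))
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=3)
        dx = np.zeros(self._shape)
        dx[:, :, : 2 * L2] = dxr.reshape(N, C, 2 * L2)
        return dx


class Conv2D(Layer):
    """'same' 2-D convolution, stride 1, odd square kernel. Input (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.W = he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = (self.W, self.b)
        self.grads = (self.dW, self.db)

    def forward(self, x: Array) -> Array:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        self._cols = cols
        self._hw = x.shape[2:]
        y = np.einsum("nchwij,ocij->nohw", cols, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, grad: Array) -> Array:
        k, p = self.k, self.k // 2
        H, W = self._hw
        self.dW[...] = np.einsum("nohw,nchwij->ocij", grad, self._cols, optimize=True)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        dxp = np.zeros((grad.shape[0], self.W.shape[1], H + 2 * p, W + 2 * p))
        t = np.einsum("nohw,ocij->ncijhw", grad, self.W, optimize=True)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += t[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling; odd tails dropped."""

    def forward(self, x: Array) -> Array:
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        self._shape = x.shape
        xr = (
            x[:, :, : 2 * H2, : 2 * W2]
            .reshape(N, C, H2, 2, W2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H2, W2, 4)
        )
        self._idx = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, grad: Array) -> Array:
        N, C, H, W = self._shape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((N, C, H2, W2, 4))
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=4)
        dx = np.zeros(self._shape)
        dx[:, :, : 2 * H2, : 2 * W2] = (
            dxr.reshape(N, C, H2, W2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, 2 * H2, 2 * W2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: Array) -> Array:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: Array) -> Array:
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: Array) -> Array:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: Array) -> Array:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_pairs(self) -> list[tuple[Array, Array]]:
        pairs = []
        for layer in self.layers:
            pairs.extend(zip(layer.params, layer.grads))
        return pairs

    def param_arrays(self) -> list[Array]:
        return [p for p, _ in self.param_pairs()]


class Adam:
    """Adam over (param, grad) array pairs; updates parameters in place."""

    def __init__(self, pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(pairs)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Array, labels: Array) -> tuple[float, Array]:
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def sigmoid(x: Array) -> Array:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Array, targets: Array) -> tuple[Array, Array]:
    """Elementwise binary cross-entropy; returns (losses, dlogits)."""
    p = sigmoid(logits)
    losses = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    return losses, p - targets


def smooth_l1(diff: Array) -> tuple[Array, Array]:
    """Elementwise smooth-L1 (Huber, delta=1); returns (losses, dgrads)."""
    a = np.abs(diff)
    losses = np.where(a < 1, 0.5 * diff * diff, a - 0.5)
    grads = np.clip(diff, -1.0, 1.0)
    return losses, grads
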