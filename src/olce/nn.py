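"""Minimal numpy neural-network layers with explicit backpropagation.

Implements exactly the operations the encoder-decoder architecture needs:
valid 1-D convolution, ReLU, width-2 max-pooling that records argmax
indices, flatten, fully-connected layers, index-based max-unpooling, and
1-D transposed convolution, plus an Adam optimizer.  All layers operate on
batches shaped (N, C, L) and every backward pass is verified against
numeric differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Valid (no padding, stride 1) 1-D convolution, (N, Cin, L) -> (N, Cout, L-k+1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, (out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = sliding_window_view(x, self.k, axis=2)  # (N, Cin, Lout, k)
        return np.einsum("nilk,oik->nol", win, self.W, optimize=True) + self.b[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win = sliding_window_view(self._x, self.k, axis=2)
        self.grads[0][...] = np.einsum("nol,nilk->oik", grad, win, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        k = self.k
        gpad = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = sliding_window_view(gpad, k, axis=2)  # (N, Cout, Lin, k)
        wflip = self.W[:, :, ::-1]
        return np.einsum("nolk,oik->nil", gwin, wflip, optimize=True)


class ConvTranspose1d(Layer):
    """Stride-1 transposed convolution, (N, Cin, L) -> (N, Cout, L+k-1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, (in_channels, out_channels, kernel))
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.k
        xpad = np.pad(x, ((0, 0), (0, 0), (k - 1, k - 1)))
        xwin = sliding_window_view(xpad, k, axis=2)  # (N, Cin, Lout, k)
        wflip = self.W[:, :, ::-1]
        return np.einsum("nilk,iok->nol", xwin, wflip, optimize=True) + self.b[:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gwin = sliding_window_view(grad, self.k, axis=2)  # (N, Cout, Lin, k)
        self.grads[0][...] = np.einsum("nis,nosk->iok", self._x, gwin, optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        return np.einsum("nosk,iok->nis", gwin, self.W, optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Width-2, stride-2 max pooling; records argmax indices for unpooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        if l % 2:
            raise ValueError(f"max-pool input length {l} is odd")
        pairs = x.reshape(n, c, l // 2, 2)
        self.indices = pairs.argmax(axis=3)  # ties -> earlier position
        self._in_len = l
        return pairs.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, lo = grad.shape
        out = np.zeros((n, c, lo, 2))
        np.put_along_axis(out, self.indices[..., None], grad[..., None], axis=3)
        return out.reshape(n, c, self._in_len)


class MaxUnpool1d(Layer):
    """Index-based unpooling: each value is placed at the position its paired
    pooling layer selected; the other slot stays zero."""

    def __init__(self, source: MaxPool1d) -> None:
        super().__init__()
        self.source = source

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        idx = self.source.indices
        if idx.shape != x.shape:
            raise ValueError(
                f"unpool input {x.shape} does not match pooling indices {idx.shape}"
            )
        out = np.zeros((n, c, l, 2))
        np.put_along_axis(out, idx[..., None], x[..., None], axis=3)
        return out.reshape(n, c, 2 * l)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l2 = grad.shape
        pairs = grad.reshape(n, c, l2 // 2, 2)
        return np.take_along_axis(pairs, self.source.indices[..., None], axis=3)[..., 0]


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Unflatten(Layer):
    def __init__(self, channels: int, length: int) -> None:
        super().__init__()
        self.channels, self.length = channels, length

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(grad.shape[0], -1)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, scale, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def softmax_vjp(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Backprop dL/dp through the softmax to its logits: p * (dp - <dp, p>)."""
    return p * (dp - (dp * p).sum(axis=1, keepdims=True))


def cross_entropy(p: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    eps = 1e-12
    return float(-np.log(p[np.arange(len(labels)), labels] + eps).mean())


class Adam:
    """Adaptive-moment gradient optimizer over a flat list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
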