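"""Minimal CPU neural-network engine used by the two-channel classifier.

Implements exactly the layer set the classifier needs — 2-D/1-D "same"
convolution, batch normalization, ReLU, 2x max-pooling, inverted dropout,
dense layers and a softmax/cross-entropy loss — with explicit forward and
backward passes over numpy arrays and plain SGD updates.  Every stochastic
element (initialization, dropout masks) draws from a generator owned by the
model, so a seed fully determines training.  Gradients are verified against
numerical differentiation in the test suite.

Array layouts: images are (N, C, H, W); signatures are (N, C, L).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool2D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(onehot * np.log(p + eps), axis=1))
    grad = (p - onehot) / logits.shape[0]
    return float(loss), grad


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts if trainable."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) same-padded, stride-1 2-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, train):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        windows = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        self._cols, self._shape = cols, (n, c, h, w)
        y = cols @ self.params["W"].T + self.params["b"]
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._shape
        p, k = self.k // 2, self.k
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads["W"] = dy_flat.T @ self._cols
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class Conv1D(Layer):
    """Length-5 (configurable) same-padded, stride-1 1-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, train):
        n, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        windows = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, k)
        cols = windows.transpose(0, 2, 1, 3).reshape(n * length, c * self.k)
        self._cols, self._shape = cols, (n, c, length)
        y = cols @ self.params["W"].T + self.params["b"]
        return y.reshape(n, length, self.out_ch).transpose(0, 2, 1)

    def backward(self, dy):
        n, c, length = self._shape
        p, k = self.k // 2, self.k
        dy_flat = dy.transpose(0, 2, 1).reshape(n * length, self.out_ch)
        self.grads["W"] = dy_flat.T @ self._cols
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"]).reshape(n, length, c, k)
        dxp = np.zeros((n, c, length + 2 * p))
        for ki in range(k):
            dxp[:, :, ki : ki + length] += dcols[:, :, :, ki].transpose(0, 2, 1)
        return dxp[:, :, p : p + length]


class BatchNorm(Layer):
    """Per-channel batch normalization for (N, C, ...) tensors.

    Training uses batch statistics and maintains exponential running
    estimates (momentum 0.1) for inference.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_ch)
        self.params["beta"] = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes, bshape = self._axes(x), self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
        self._xhat, self._std, self._train = xhat, std, train
        return self.params["gamma"].reshape(bshape) * xhat + self.params["beta"].reshape(bshape)

    def backward(self, dy):
        axes, bshape = self._axes(dy), self._bshape(dy)
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(bshape)
        if not self._train:
            return dy * g / std.reshape(bshape)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(bshape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(bshape)
        ) / std.reshape(bshape)
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling (dimensions must be even)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dblocks, self._argmax[..., None], dy[..., None], axis=-1)
        dblocks = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dblocks.reshape(n, c, h, w)


class MaxPool1D(Layer):
    """Non-overlapping size-2 max pooling along the last axis."""

    def forward(self, x, train):
        n, c, length = x.shape
        if length % 2:
            raise ValueError("length must be even for size-2 pooling")
        blocks = x.reshape(n, c, length // 2, 2)
        self._argmax = blocks.argmax(axis=-1)
        self._shape = (n, c, length)
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, length = self._shape
        dblocks = np.zeros((n, c, length // 2, 2))
        np.put_along_axis(dblocks, self._argmax[..., None], dy[..., None], axis=-1)
        return dblocks.reshape(n, c, length)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential:
    """A forward/backward chain of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def trainable_layers(self):
        return [l for l in self.layers if l.params]

    def output_shapes(self, input_shape: tuple[int, ...]) -> list[tuple[int, ...]]:
        """Per-layer output shapes for a batch of one (dummy forward)."""
        x = np.zeros((1,) + tuple(input_shape))
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes.append(x.shape[1:])
        return shapes


def sgd_step(layers, lr: float) -> None:
    for layer in layers:
        for key, g in layer.grads.items():
            layer.params[key] -= lr * g


def collect_weights(layers) -> list[dict[str, np.ndarray]]:
    out = []
    for layer in layers:
        state = {k: v.copy() for k, v in layer.params.items()}
        if isinstance(layer, BatchNorm):
            state["__running_mean"] = layer.running_mean.copy()
            state["__running_var"] = layer.running_var.copy()
        out.append(state)
    return out


def restore_weights(layers, snapshot) -> None:
    for layer, state in zip(layers, snapshot):
        for k in layer.params:
            layer.params[k] = state[k].copy()
        if isinstance(layer, BatchNorm):
            layer.running_mean = state["__running_mean"].copy()
            layer.running_var = state["__running_var"].copy()
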