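"""Minimal float CNN layers with backprop, for the synthetic fixture models.

This is deliberately a small, plain-numpy network framework: the package
needs miniature float models with realistic weight distributions to feed the
quantizer, plus a gradient-descent loop good enough to fit the synthetic
texture-classification task.  Data layout is NCHW; convolutions go through
im2col.  Supported layer kinds mirror the fixed-point simulator: conv2d,
depthwise_conv2d, linear, batchnorm (inference-style affine), relu, relu6,
global average pooling, flatten and residual blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Conv2d",
    "DepthwiseConv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "ReLU6",
    "GlobalAvgPool",
    "Flatten",
    "ResidualBlock",
    "FloatModel",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    cols = np.empty((n, c * kh * kw, ho * wo), dtype=x.dtype)
    idx = 0
    for ci in range(c):
        for i in range(kh):
            for j in range(kw):
                patch = x[:, ci, i : i + stride * ho : stride, j : j + stride * wo : stride]
                cols[:, idx, :] = patch.reshape(n, -1)
                idx += 1
    return cols, ho, wo


def _col2im(grad_cols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    gx = np.zeros((n, c, hp, wp), dtype=grad_cols.dtype)
    idx = 0
    for ci in range(c):
        for i in range(kh):
            for j in range(kw):
                gx[:, ci, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    grad_cols[:, idx, :].reshape(n, ho, wo)
                )
                idx += 1
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    kind = "conv2d"

    def __init__(self, c_in, c_out, k=3, stride=1, pad=0, rng=None, init="he_scaled"):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in) if init == "he_scaled" else 0.1
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        if train:
            self._cols = cols
        wmat = self.params["w"].reshape(self.c_out, -1)
        out = np.einsum("of,nfl->nol", wmat, cols) + self.params["b"][None, :, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, grad):
        n, co, ho, wo = grad.shape
        g = grad.reshape(n, co, ho * wo)
        wmat = self.params["w"].reshape(self.c_out, -1)
        self.grads["w"] = np.einsum("nol,nfl->of", g, self._cols).reshape(self.params["w"].shape) / n
        self.grads["b"] = g.sum(axis=(0, 2)) / n
        gcols = np.einsum("of,nol->nfl", wmat, g)
        return _col2im(gcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class DepthwiseConv2d(Layer):
    kind = "depthwise_conv2d"

    def __init__(self, c, k=3, stride=1, pad=0, rng=None, init="he_scaled"):
        super().__init__()
        self.c, self.k, self.stride, self.pad = c, k, stride, pad
        scale = np.sqrt(2.0 / (k * k)) if init == "he_scaled" else 0.1
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, scale, size=(c, k, k))
        self.params["b"] = np.zeros(c)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        cols = cols.reshape(n, c, self.k * self.k, ho * wo)
        if train:
            self._cols = cols
        wmat = self.params["w"].reshape(c, -1)
        out = np.einsum("cf,ncfl->ncl", wmat, cols) + self.params["b"][None, :, None]
        return out.reshape(n, c, ho, wo)

    def backward(self, grad):
        n, c, ho, wo = grad.shape
        g = grad.reshape(n, c, ho * wo)
        self.grads["w"] = np.einsum("ncl,ncfl->cf", g, self._cols).reshape(self.params["w"].shape) / n
        self.grads["b"] = g.sum(axis=(0, 2)) / n
        wmat = self.params["w"].reshape(c, -1)
        gcols = np.einsum("cf,ncl->ncfl", wmat, g).reshape(n, c * self.k * self.k, ho * wo)
        return _col2im(gcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class Linear(Layer):
    kind = "linear"

    def __init__(self, d_in, d_out, rng=None, init="he_scaled"):
        super().__init__()
        scale = np.sqrt(2.0 / d_in) if init == "he_scaled" else 0.1
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, scale, size=(d_out, d_in))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad):
        n = grad.shape[0]
        self.grads["w"] = grad.T @ self._x / n
        self.grads["b"] = grad.mean(axis=0)
        return grad @ self.params["w"]


class BatchNorm2d(Layer):
    """Inference-style per-channel affine y = gamma*(x-mean)/sqrt(var+eps)+beta.

    Statistics are fixed parameters here (the fixtures never train them);
    the quantizer folds them into a Q-format scale and shift.
    """

    kind = "batchnorm"

    def __init__(self, c, gamma=None, beta=None, mean=None, var=None, eps=1e-5):
        super().__init__()
        self.c, self.eps = c, eps
        self.params["gamma"] = np.ones(c) if gamma is None else np.asarray(gamma, float)
        self.params["beta"] = np.zeros(c) if beta is None else np.asarray(beta, float)
        self.mean = np.zeros(c) if mean is None else np.asarray(mean, float)
        self.var = np.ones(c) if var is None else np.asarray(var, float)

    def scale_shift(self):
        scale = self.params["gamma"] / np.sqrt(self.var + self.eps)
        shift = self.params["beta"] - self.mean * scale
        return scale, shift

    def forward(self, x, train=False):
        scale, shift = self.scale_shift()
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def backward(self, grad):
        scale, _ = self.scale_shift()
        return grad * scale[None, :, None, None]


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class ReLU6(Layer):
    kind = "relu6"

    def forward(self, x, train=False):
        if train:
            self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    kind = "avgpool"

    def forward(self, x, train=False):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, grad):
        n, c, h, w = self._x_shape
        return np.broadcast_to(grad / (h * w), self._x_shape).copy()


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, train=False):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._x_shape)


class ResidualBlock(Layer):
    """y = x + f(x) with f a short sequential branch (inverted-residual style)."""

    kind = "residual_add"

    def __init__(self, branch: Sequence[Layer]):
        super().__init__()
        self.branch = list(branch)

    def forward(self, x, train=False):
        y = x
        for layer in self.branch:
            y = layer.forward(y, train=train)
        return x + y

    def backward(self, grad):
        g = grad
        for layer in reversed(self.branch):
            g = layer.backward(g)
        return grad + g

    def iter_layers(self):
        return iter(self.branch)


class FloatModel:
    """An ordered list of float layers with a softmax cross-entropy head."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def parameters(self):
        def walk(layers):
            for layer in layers:
                if isinstance(layer, ResidualBlock):
                    yield from walk(layer.branch)
                elif layer.params:
                    yield layer
        return list(walk(self.layers))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward(x, train=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        n = x.shape[0]
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        grad = probs
        grad[np.arange(n), y] -= 1.0
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return float(loss)
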