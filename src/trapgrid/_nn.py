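"""Minimal CNN engine: layers, backprop and Adam on numpy arrays.

Implements exactly the pieces the grid detector needs — 2-D convolution,
batch normalisation, ReLU, max-pooling, inverted dropout, residual blocks
and a per-cell weighted softmax cross-entropy — in NCHW float32 layout.
Forward passes cache what the backward pass needs; calling ``backward``
before ``forward`` is a programming error.

Convolutions are evaluated as a sum over kernel offsets of strided slices
(no im2col buffer), which keeps memory flat and is fast at the patch sizes
used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Dropout",
    "BasicBlock",
    "Sequential",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He-normal, matches ReLU activations
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._xp: np.ndarray | None = None

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(f"input {h}x{w} too small for kernel {k} stride {s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp if train else None
        self._oshape = (n, oh, ow)
        W = self.weight.data
        out = np.zeros((n, W.shape[0], oh, ow), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
                out += np.einsum("nchw,oc->nohw", xs, W[:, :, ki, kj], optimize=True)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, dy):
        if self._xp is None:
            raise RuntimeError("backward before forward(train=True)")
        k, s, p = self.kernel, self.stride, self.padding
        xp = self._xp
        n, oh, ow = self._oshape
        W = self.weight.data
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
                self.weight.grad[:, :, ki, kj] += np.einsum(
                    "nohw,nchw->oc", dy, xs, optimize=True)
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += np.einsum(
                    "nohw,oc->nchw", dy, W[:, :, ki, kj], optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._xp = None
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, ivar = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        # standard batch-norm backward, vectorised per channel
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - t1 / m - xhat * t2 / m) * ivar[None, :, None, None]
        return dx.astype(np.float32)

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        out = np.full((n, c, oh, ow), -np.inf, dtype=np.float32)
        arg = np.zeros((n, c, oh, ow), dtype=np.int8)
        for idx in range(k * k):
            ki, kj = divmod(idx, k)
            xs = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
            better = xs > out
            out[better] = xs[better]
            arg[better] = idx
        if train:
            self._arg, self._xshape, self._oshape = arg, x.shape, (oh, ow)
        return out

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = self._xshape
        oh, ow = self._oshape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for idx in range(k * k):
            ki, kj = divmod(idx, k)
            dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += dy * (self._arg == idx)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Dropout(Layer):
    """Inverted dropout; identity at inference so prediction is deterministic."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self.p == 0.0:
            return dy
        return (dy * self._mask).astype(np.float32)


class BasicBlock(Layer):
    """Two 3x3 convs with batch norm and an (optionally projected) skip path."""

    def __init__(self, c_in: int, c_out: int, stride: int, *, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj: tuple | None = (Conv2d(c_in, c_out, 1, stride, 0,
                                              bias=False, rng=rng),
                                       BatchNorm2d(c_out))
        else:
            self.proj = None
        self.relu_out = ReLU()

    def forward(self, x, train):
        y = self.bn1.forward(self.conv1.forward(x, train), train)
        y = self.relu1.forward(y, train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.proj is not None:
            sc = self.proj[1].forward(self.proj[0].forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(
            self.relu1.backward(
                self.bn1.backward(
                    self.conv2.backward(self.bn2.backward(dsum)))))
        if self.proj is not None:
            dx_skip = self.proj[0].backward(self.proj[1].backward(dsum))
        else:
            dx_skip = dsum
        return dx_main + dx_skip

    def parameters(self):
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            ps += self.proj[0].parameters() + self.proj[1].parameters()
        return ps


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def parameters(self):
        return [p for lay in self.layers for p in lay.parameters()]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray):
    """Per-cell weighted cross entropy on an (N, C, H, W) logit grid.

    Returns ``(loss, dlogits)`` where the loss is the weighted mean of the
    per-cell negative log-likelihoods (weights normalised so the loss is a
    weighted average, not a sum).
    """
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    flat_p = p.transpose(0, 2, 3, 1).reshape(-1, c)
    flat_y = labels.reshape(-1)
    wts = class_weights[flat_y].astype(np.float64)
    wsum = wts.sum()
    nll = -np.log(np.maximum(flat_p[np.arange(flat_p.shape[0]), flat_y], 1e-12))
    loss = float((wts * nll).sum() / wsum)
    onehot = np.zeros_like(flat_p)
    onehot[np.arange(flat_p.shape[0]), flat_y] = 1.0
    dflat = (flat_p - onehot) * (wts / wsum)[:, None]
    dlogits = dflat.reshape(n, h, w, c).transpose(0, 3, 1, 2).astype(np.float32)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
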