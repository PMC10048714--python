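"""Minimal NumPy neural-network layers with manual backpropagation.

Everything runs on float32 NCHW arrays.  Convolutions are computed as a
sum of per-kernel-offset matrix products over strided slices of the
padded input, which avoids materialising im2col buffers and keeps the
memory footprint of full-scale forward passes small.  Each layer caches
what its backward pass needs only while in training mode, so evaluation
forward passes are cache-free.

The framework is deliberately small: exactly the pieces the pear-fusion
backbones need (plain/depthwise convolution, batch norm, ReLU, max/avg
pooling, global average pooling, dense) plus Adam and a softmax
cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Sequential", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "ReLU", "MaxPool2d", "AvgPool2d", "GlobalAvgPool",
    "Dense", "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


class Module:
    """Base class: children tracking, parameter collection, train/eval mode."""

    def __init__(self):
        self.training = True

    def children(self):
        return []

    def params(self):
        out = []
        for ch in self.children():
            out.extend(ch.params())
        return out

    def set_training(self, flag: bool):
        self.training = flag
        for ch in self.children():
            ch.set_training(flag)
        return self

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


class Conv2d(Module):
    """2-D convolution (cross-correlation), He-normal initialised."""

    def __init__(self, c_in, c_out, k, stride=1, pad=None, bias=True, rng=None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, stride
        self.p = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        OH, OW = _out_size(H, k, s, p), _out_size(W, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((N, self.c_out, OH, OW), dtype=np.float32)
        wmat = self.w.v.reshape(self.c_out, self.c_in, k * k)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + s * OH:s, v:v + s * OW:s]
                # (O,C) @ (N,C,OH*OW) -> (N,O,OH*OW)
                out += np.einsum(
                    "oc,ncp->nop", wmat[:, :, u * k + v],
                    xs.reshape(N, C, OH * OW), optimize=True,
                ).reshape(N, self.c_out, OH, OW)
        if self.b is not None:
            out += self.b.v[None, :, None, None]
        if self.training:
            self._cache = (xp, x.shape)
        return out

    def backward(self, grad):
        xp, xshape = self._cache
        N, C, H, W = xshape
        k, s, p = self.k, self.s, self.p
        OH, OW = grad.shape[2], grad.shape[3]
        g = grad.reshape(N, self.c_out, OH * OW)
        gxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + s * OH:s, v:v + s * OW:s].reshape(N, C, OH * OW)
                self.w.g[:, :, u, v] += np.einsum("nop,ncp->oc", g, xs, optimize=True)
                gxp[:, :, u:u + s * OH:s, v:v + s * OW:s] += np.einsum(
                    "oc,nop->ncp", self.w.v[:, :, u, v], g, optimize=True
                ).reshape(N, C, OH, OW)
        if self.b is not None:
            self.b.g += grad.sum(axis=(0, 2, 3))
        self._cache = None
        return gxp[:, :, p:H + p, p:W + p] if p else gxp


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (the spatial half of a separable conv)."""

    def __init__(self, c, k, stride=1, pad=None, rng=None):
        super().__init__()
        self.c, self.k, self.s = c, k, stride
        self.p = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k))
        self.w = Param(rng.normal(0.0, std, size=(c, k, k)))
        self.b = Param(np.zeros(c))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        OH, OW = _out_size(H, k, s, p), _out_size(W, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((N, C, OH, OW), dtype=np.float32)
        for u in range(k):
            for v in range(k):
                out += xp[:, :, u:u + s * OH:s, v:v + s * OW:s] * \
                    self.w.v[None, :, u, v, None, None]
        out += self.b.v[None, :, None, None]
        if self.training:
            self._cache = (xp, x.shape)
        return out

    def backward(self, grad):
        xp, xshape = self._cache
        N, C, H, W = xshape
        k, s, p = self.k, self.s, self.p
        OH, OW = grad.shape[2], grad.shape[3]
        gxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + s * OH:s, v:v + s * OW:s]
                self.w.g[:, u, v] += np.einsum("nchw,nchw->c", xs, grad, optimize=True)
                gxp[:, :, u:u + s * OH:s, v:v + s * OW:s] += \
                    grad * self.w.v[None, :, u, v, None, None]
        self.b.g += grad.sum(axis=(0, 2, 3))
        self._cache = None
        return gxp[:, :, p:H + p, p:W + p] if p else gxp


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if self.training:
            self._cache = (xhat, std)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, grad):
        xhat, std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.g += np.einsum("nchw,nchw->c", grad, xhat, optimize=True)
        self.beta.g += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.v[None, :, None, None]
        mean_g = gxhat.mean(axis=(0, 2, 3))
        mean_gx = np.einsum("nchw,nchw->c", gxhat, xhat, optimize=True) / m
        gx = (gxhat - mean_g[None, :, None, None]
              - xhat * mean_gx[None, :, None, None]) / std[None, :, None, None]
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        out = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return out

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2d(Module):
    def __init__(self, k, stride=None, pad=0):
        super().__init__()
        self.k, self.s, self.p = k, stride or k, pad

    def forward(self, x):
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        OH, OW = _out_size(H, k, s, p), _out_size(W, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        stacked = np.stack([
            xp[:, :, u:u + s * OH:s, v:v + s * OW:s]
            for u in range(k) for v in range(k)
        ])  # (k*k, N, C, OH, OW)
        idx = stacked.argmax(axis=0)
        out = np.take_along_axis(stacked, idx[None], axis=0)[0]
        if self.training:
            self._cache = (idx, xp.shape, (N, C, H, W), OH, OW)
        return out

    def backward(self, grad):
        idx, xpshape, xshape, OH, OW = self._cache
        k, s, p = self.k, self.s, self.p
        gxp = np.zeros(xpshape, dtype=np.float32)
        for flat in range(k * k):
            u, v = divmod(flat, k)
            mask = idx == flat
            sl = gxp[:, :, u:u + s * OH:s, v:v + s * OW:s]
            sl += np.where(mask, grad, 0.0)
        N, C, H, W = xshape
        self._cache = None
        return gxp[:, :, p:H + p, p:W + p] if p else gxp


class AvgPool2d(Module):
    """Non-overlapping average pooling (k == stride, dims divisible by k)."""

    def __init__(self, k):
        super().__init__()
        self.k = k

    def forward(self, x):
        N, C, H, W = x.shape
        k = self.k
        if H % k or W % k:
            raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {k}")
        out = x.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))
        if self.training:
            self._shape = (N, C, H, W)
        return out

    def backward(self, grad):
        N, C, H, W = self._shape
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        self._shape = None
        return g.astype(np.float32)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""

    def forward(self, x):
        if self.training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._shape
        self._shape = None
        return (np.broadcast_to(grad[:, :, None, None], (N, C, H, W)) / (H * W)
                ).astype(np.float32)


class Dense(Module):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        # Glorot-uniform initialisation
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = Param(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self.training:
            self._x = x
        return x @ self.w.v + self.b.v

    def backward(self, grad):
        self.w.g += self._x.T @ grad
        self.b.g += grad.sum(axis=0)
        gx = grad @ self.w.v.T
        self._x = None
        return gx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
    grad = probs.astype(np.float32)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimiser over a parameter list, with gradient zeroing."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.s = [np.zeros_like(p.v) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            g = p.g
            if self.weight_decay:
                g = g + self.weight_decay * p.v
            m *= self.b1
            m += (1 - self.b1) * g
            s *= self.b2
            s += (1 - self.b2) * g * g
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
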