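"""Layer objects with explicit forward/backward passes.

Each layer caches what its backward pass needs; models chain ``forward``
calls and then ``backward`` in reverse order. No autograd graph — the
architectures here (U-net, codec, MLP) are small and fixed, and the manual
chain keeps the dynamic-convolution gradient explicit and testable.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

DTYPE = F.DTYPE


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def modules(self):
        """This module and all sub-modules, depth-first."""
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        arrays = [p.data for p in self.params()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=DTYPE)
            p.grad = np.zeros_like(p.data)
        i = len(params)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(arrays[i], dtype=np.float64)
                m.running_var = np.asarray(arrays[i + 1], dtype=np.float64)
                i += 2
        if i != len(arrays):
            raise ValueError("checkpoint array count mismatch")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    """Plain same-padding stride-1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.weight = Param(_he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.bias = Param(np.zeros(out_ch))

    def forward(self, x):
        y, self._cache = F.conv2d_forward(x, self.weight.data, self.bias.data)
        return y

    def backward(self, dy):
        dx, dw, db = F.conv2d_backward(dy, self._cache)
        self.weight.grad += dw
        self.bias.grad += db
        return dx


class DynamicConv2d(Module):
    """Convolution whose kernel is an attention-weighted sum of N candidates.

    A squeeze-and-excitation block (global average pool -> FC -> ReLU ->
    FC -> softmax) maps each input to weights ``w_1..w_N`` with
    ``sum_i w_i = 1``; the layer convolves with ``sum_i w_i * conv_i`` (and
    the same aggregation of the per-kernel biases). The effective kernel
    therefore adapts per input sample.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, n_kernels: int,
                 rng: np.random.Generator, temperature: float = 1.0,
                 attn_hidden: int | None = None):
        if n_kernels < 1:
            raise ValueError(f"n_kernels must be >= 1, got {n_kernels}")
        if temperature <= 0:
            raise ValueError("softmax temperature must be positive")
        self.n_kernels = n_kernels
        self.temperature = float(temperature)
        hidden = attn_hidden or max(4, in_ch // 4)
        self.kernels = Param(_he_init(rng, (n_kernels, out_ch, in_ch, k, k), in_ch * k * k))
        self.kbias = Param(np.zeros((n_kernels, out_ch)))
        self.attn_w1 = Param(_he_init(rng, (hidden, in_ch), in_ch))
        self.attn_b1 = Param(np.zeros(hidden))
        self.attn_w2 = Param(_he_init(rng, (n_kernels, hidden), hidden))
        self.attn_b2 = Param(np.zeros(n_kernels))

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Per-sample kernel weights, shape (N_batch, n_kernels); rows sum to 1."""
        s = x.mean(axis=(2, 3))
        h = s @ self.attn_w1.data.T + self.attn_b1.data
        hr = np.maximum(h, 0.0)
        logits = hr @ self.attn_w2.data.T + self.attn_b2.data
        w = F.softmax(logits / self.temperature, axis=1)
        self._attn_cache = (x.shape, s, h, hr, w)
        return w

    def forward(self, x):
        w = self.attention(x)
        n = x.shape[0]
        # per-sample aggregated kernel and bias (Eq.-9 style superposition)
        kag = np.einsum("nk,kocuv->nocuv", w, self.kernels.data, optimize=True)
        bag = w @ self.kbias.data
        ys, caches = [], []
        for i in range(n):
            y, c = F.conv2d_forward(x[i:i + 1], kag[i].astype(DTYPE), bag[i].astype(DTYPE))
            ys.append(y)
            caches.append(c)
        self._cache = (caches, kag, w)
        return np.concatenate(ys, axis=0)

    def backward(self, dy):
        caches, kag, w = self._cache
        xshape, s, h, hr, _ = self._attn_cache
        n = dy.shape[0]
        dx = np.empty(xshape, dtype=DTYPE)
        dkag = np.empty_like(kag)
        dbag = np.empty((n, self.kbias.data.shape[1]), dtype=np.float64)
        for i in range(n):
            dxi, dwi, dbi = F.conv2d_backward(dy[i:i + 1], caches[i])
            dx[i] = dxi[0]
            dkag[i] = dwi
            dbag[i] = dbi
        # candidate-kernel gradients: each candidate gets its attention share
        self.kernels.grad += np.einsum("nk,nocuv->kocuv", w, dkag, optimize=True).astype(DTYPE)
        self.kbias.grad += (w.T @ dbag).astype(DTYPE)
        # gradient w.r.t. the attention weights themselves
        dw = np.einsum("nocuv,kocuv->nk", dkag, self.kernels.data, optimize=True)
        dw += dbag @ self.kbias.data.T
        # softmax (with temperature) backward
        dlogits = (dw - (dw * w).sum(axis=1, keepdims=True)) * w / self.temperature
        self.attn_w2.grad += (dlogits.T @ hr).astype(DTYPE)
        self.attn_b2.grad += dlogits.sum(axis=0).astype(DTYPE)
        dhr = dlogits @ self.attn_w2.data
        dh = dhr * (h > 0)
        self.attn_w1.grad += (dh.T @ s).astype(DTYPE)
        self.attn_b1.grad += dh.sum(axis=0).astype(DTYPE)
        ds = dh @ self.attn_w1.data
        # squeeze path: mean over H*W broadcasts back uniformly
        hw = xshape[2] * xshape[3]
        dx += (ds / hw)[:, :, None, None].astype(DTYPE)
        return dx


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Param(_he_init(rng, (out_dim, in_dim), in_dim))
        self.bias = Param(np.zeros(out_dim))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy):
        self.weight.grad += (dy.T @ self._x).astype(DTYPE)
        self.bias.grad += dy.sum(axis=0).astype(DTYPE)
        return (dy @ self.weight.data).astype(DTYPE)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat.astype(DTYPE), inv, x.shape)
        y = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        return y.astype(DTYPE)

    def backward(self, dy):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3)).astype(DTYPE)
        self.beta.grad += dy.sum(axis=(0, 2, 3)).astype(DTYPE)
        dxhat = dy * self.gamma.data[:, None, None]
        if not self.training:
            return (dxhat * inv[:, None, None]).astype(DTYPE)
        # standard batch-norm backward
        t1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = (inv[:, None, None] / m) * (m * dxhat - t1 - xhat * t2)
        return dx.astype(DTYPE)


class Sigmoid(Module):
    def forward(self, x):
        self._y = F.sigmoid(x).astype(DTYPE)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2(Module):
    def forward(self, x):
        y, self._mask = F.maxpool2_forward(x)
        return y

    def backward(self, dy):
        return F.maxpool2_backward(dy, self._mask)


class Upsample2(Module):
    def forward(self, x):
        return F.upsample2_forward(x)

    def backward(self, dy):
        return F.upsample2_backward(dy)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(DTYPE)


class SGD:
    """Stochastic gradient descent with optional momentum and global
    gradient-norm clipping (guards against the occasional loss spike that
    would otherwise blow up float32 training)."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 max_grad_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64)**2))
                                for p in self.params))
            if total > self.max_grad_norm:
                scale = DTYPE(self.max_grad_norm / (total + 1e-12))
                for p in self.params:
                    p.grad *= scale
        for p, v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.data += v
            else:
                p.data -= self.lr * p.grad
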