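"""Minimal CNN building blocks on numpy + numba (float32).

The convolutional stack runs channel-major, (C, N, H, W): GEMMs go through
BLAS, while im2col, the backward fold, batch-norm, ReLU, pooling and the
attention poolings are fused single-pass numba kernels
(:mod:`yeastfish.phasecnn._kernels`), which is what keeps single-core
training within minutes.  ``ToChannelMajor`` adapts the NCHW entry point
and ``Flatten`` returns to (N, features) for the dense head.  Each layer
caches what its hand-derived backward pass needs and exposes parameters as
:class:`Param` (value + gradient) for the optimizer.

Tie-breaking in every max (pooling, attention poolings) takes the first
maximum, so forward and backward passes are deterministic.
"""

from __future__ import annotations

import numpy as np

from yeastfish.phasecnn import _kernels as K


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class ToChannelMajor(Layer):
    """(N, C, H, W) -> (C, N, H, W) at the network entry."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return _f32(x.transpose(1, 0, 2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return _f32(grad.transpose(1, 0, 2, 3))


class Conv2d(Layer):
    """Same-padding 2-D convolution, stride 1, on (C, N, H, W) data."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.standard_normal((cout, cin * k * k)) * scale)
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x_shape = x.shape
        c, n, h, w = x.shape
        self.cols = K.im2col(_f32(x), self.k)
        y = self.w.value @ self.cols
        y += self.b.value[:, None]
        return y.reshape(self.cout, n, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, n, h, w = self.x_shape
        gm = _f32(grad).reshape(self.cout, n * h * w)
        self.w.grad += gm @ self.cols.T
        self.b.grad += gm.sum(axis=1)
        dcols = self.w.value.T @ gm
        return K.col_fold(dcols, c, n, h, w, self.k)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[0]
        x = _f32(x)
        if train:
            mean, var = K.bn_stats(x)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self.invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self.mean = mean.astype(np.float32)
        self.x = x  # xhat is recomputed inside the backward kernels
        self.train_mode = train
        scale = self.invstd * self.gamma.value
        shift = self.beta.value - self.mean * scale
        return K.bn_forward(x, scale, shift)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _f32(grad)
        c = grad.shape[0]
        m = grad.size // c
        s1, s2 = K.bn_backward_stats(grad, self.x, self.mean, self.invstd)
        self.gamma.grad += s2
        self.beta.grad += s1
        if not self.train_mode:
            scale = self.gamma.value * self.invstd
            return K.bn_forward(grad, scale, np.zeros_like(scale))
        mean_g = self.gamma.value * s1 / m
        mean_gx = self.gamma.value * s2 / m
        return K.bn_backward_apply(
            grad, self.x, self.mean, self.invstd, self.gamma.value, mean_g, mean_gx
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.out = K.relu_forward(_f32(x))
        return self.out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return K.relu_backward(self.out, _f32(grad))


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, on (C, N, H, W); odd edges dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.in_hw = x.shape[2:]
        out, self.idx = K.maxpool_forward(_f32(x))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return K.maxpool_backward(_f32(grad), self.idx, *self.in_hw)


class ChannelAttention(Layer):
    """CBAM channel gate: average- and max-pooled channel descriptors
    through a shared two-layer MLP, summed, sigmoid-scaled."""

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 8):
        hidden = max(c // reduction, 4)
        self.w1 = Param(rng.standard_normal((hidden, c)) * np.sqrt(2.0 / c))
        self.b1 = Param(np.zeros(hidden))
        self.w2 = Param(rng.standard_normal((c, hidden)) * np.sqrt(2.0 / hidden))
        self.b2 = Param(np.zeros(c))

    def _mlp(self, s: np.ndarray):
        h_pre = s @ self.w1.value.T + self.b1.value
        h = np.maximum(h_pre, 0.0)
        return h_pre, h, h @ self.w2.value.T + self.b2.value

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = _f32(x)
        self.x = x
        mean_cn, max_cn, self.arg = K.channel_pool(x)
        self.s_avg = mean_cn.T  # (n, c)
        self.s_max = max_cn.T
        self.h1a_pre, self.h1a, ya = self._mlp(self.s_avg)
        self.h1m_pre, self.h1m, ym = self._mlp(self.s_max)
        self.a = _sigmoid(ya + ym).astype(np.float32)  # (n, c)
        return x * self.a.T[:, :, None, None]

    def _mlp_backward(self, ds: np.ndarray, h_pre, h, s):
        self.w2.grad += ds.T @ h
        self.b2.grad += ds.sum(axis=0)
        dh = (ds @ self.w2.value) * (h_pre > 0)
        self.w1.grad += dh.T @ s
        self.b1.grad += dh.sum(axis=0)
        return dh @ self.w1.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _f32(grad)
        da = K.channel_gate_da(grad, self.x).T  # (n, c)
        dpre = da * self.a * (1.0 - self.a)
        dsa = self._mlp_backward(dpre, self.h1a_pre, self.h1a, self.s_avg)
        dsm = self._mlp_backward(dpre, self.h1m_pre, self.h1m, self.s_max)
        return K.channel_attention_backward(
            grad,
            self.a.T.astype(np.float32),
            _f32(dsa.T),
            _f32(dsm.T),
            self.arg,
        )

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]


class SpatialAttention(Layer):
    """CBAM spatial gate: channel-wise mean and max maps through a k x k
    convolution (direct, no im2col — only two input channels) and a
    sigmoid."""

    def __init__(self, rng: np.random.Generator, k: int = 7):
        self.k = k
        scale = np.sqrt(2.0 / (2 * k * k))
        self.w = Param(rng.standard_normal(2 * k * k) * scale)
        self.b = Param(np.zeros(1))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = _f32(x)
        self.x = x
        self.s, self.arg = K.spatial_pool(x)
        pre = K.conv2_direct(self.s, self.w.value, float(self.b.value[0]), self.k)
        self.a = _sigmoid(pre)[0].astype(np.float32)  # (N, H, W)
        return x * self.a[None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _f32(grad)
        da = K.gate_mul_sum(grad, self.x)  # (N, H, W)
        dpre = _f32((da * self.a * (1.0 - self.a))[None])
        dw, db, ds = K.conv2_direct_backward(dpre, self.s, self.w.value, self.k)
        self.w.grad += dw
        self.b.grad += db
        return K.spatial_attention_backward(
            grad, self.x, self.a, _f32(ds[0]), _f32(ds[1]), self.arg
        )

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Flatten(Layer):
    """(C, N, H, W) -> (N, C * H * W)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.shape = x.shape
        c, n, h, w = x.shape
        return _f32(x.transpose(1, 0, 2, 3)).reshape(n, c * h * w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, n, h, w = self.shape
        return _f32(grad.reshape(n, c, h, w).transpose(1, 0, 2, 3))


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(rng.standard_normal((cout, cin)) * np.sqrt(2.0 / cin))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = _f32(x)
        return self.x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = _f32(grad)
        self.w.grad += grad.T @ self.x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self.mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self.mask is None else grad * self.mask


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

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
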