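"""Fused numba kernels for the memory-bound parts of the CNN.

The GEMMs run through BLAS; everything elementwise or copy-shaped around
them (im2col, the backward fold, batch-norm, ReLU, pooling, the attention
poolings) is a single fused pass here instead of several numpy
temporaries.  All kernels operate on float32 channel-major (C, N, H, W)
arrays and are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


@njit(cache=True)
def im2col(x, k):
    c, n, h, w = x.shape
    p = k // 2
    cols = np.zeros((c * k * k, n * h * w), dtype=F32)
    for ci in range(c):
        for di in range(k):
            oy = di - p
            for dj in range(k):
                ox = dj - p
                row = (ci * k + di) * k + dj
                j0 = max(0, -ox)
                j1 = w - max(0, ox)
                for ni in range(n):
                    base = ni * h * w
                    for i in range(max(0, -oy), h - max(0, oy)):
                        src = x[ci, ni, i + oy]
                        dst = base + i * w
                        for j in range(j0, j1):
                            cols[row, dst + j] = src[j + ox]
    return cols


@njit(cache=True)
def col_fold(dcols, c, n, h, w, k):
    """Adjoint of im2col: accumulate (C*k*k, N*H*W) back to (C, N, H, W)."""
    p = k // 2
    dx = np.zeros((c, n, h, w), dtype=F32)
    for ci in range(c):
        for di in range(k):
            oy = di - p
            for dj in range(k):
                ox = dj - p
                row = (ci * k + di) * k + dj
                j0 = max(0, -ox)
                j1 = w - max(0, ox)
                for ni in range(n):
                    base = ni * h * w
                    for i in range(max(0, -oy), h - max(0, oy)):
                        src = base + i * w
                        dst = dx[ci, ni, i + oy]
                        for j in range(j0, j1):
                            dst[j + ox] += dcols[row, src + j]
    return dx


@njit(cache=True)
def bn_forward(x, scale, shift):
    c = x.shape[0]
    m = x.size // c
    xf = x.reshape(c, m)
    out = np.empty_like(xf)
    for ci in range(c):
        s = scale[ci]
        t = shift[ci]
        for i in range(m):
            out[ci, i] = xf[ci, i] * s + t
    return out.reshape(x.shape)


@njit(cache=True)
def bn_backward_stats(grad, x, mean, invstd):
    """Per-channel (sum g, sum g * xhat) in one pass."""
    c = x.shape[0]
    m = x.size // c
    gf = grad.reshape(c, m)
    xf = x.reshape(c, m)
    s1 = np.zeros(c, dtype=F32)
    s2 = np.zeros(c, dtype=F32)
    for ci in range(c):
        mu = mean[ci]
        iv = invstd[ci]
        a = F32(0.0)
        b = F32(0.0)
        for i in range(m):
            g = gf[ci, i]
            a += g
            b += g * (xf[ci, i] - mu) * iv
        s1[ci] = a
        s2[ci] = b
    return s1, s2


@njit(cache=True)
def bn_backward_apply(grad, x, mean, invstd, gamma, mean_g, mean_gx):
    c = x.shape[0]
    m = x.size // c
    gf = grad.reshape(c, m)
    xf = x.reshape(c, m)
    out = np.empty_like(gf)
    for ci in range(c):
        mu = mean[ci]
        iv = invstd[ci]
        ga = gamma[ci]
        mg = mean_g[ci]
        mgx = mean_gx[ci]
        for i in range(m):
            xhat = (xf[ci, i] - mu) * iv
            out[ci, i] = (gf[ci, i] * ga - mg - xhat * mgx) * iv
    return out.reshape(x.shape)


@njit(cache=True)
def relu_forward(x):
    xf = x.ravel()
    out = np.empty_like(xf)
    for i in range(xf.size):
        v = xf[i]
        out[i] = v if v > 0 else F32(0.0)
    return out.reshape(x.shape)


@njit(cache=True)
def relu_backward(out, grad):
    of = out.ravel()
    gf = grad.ravel()
    gx = np.empty_like(gf)
    for i in range(of.size):
        gx[i] = gf[i] if of[i] > 0 else F32(0.0)
    return gx.reshape(grad.shape)


@njit(cache=True)
def maxpool_forward(x):
    c, n, h, w = x.shape
    h2, w2 = h // 2, w // 2
    out = np.empty((c, n, h2, w2), dtype=F32)
    idx = np.empty((c, n, h2, w2), dtype=np.uint8)
    for ci in range(c):
        for ni in range(n):
            for i in range(h2):
                r0 = x[ci, ni, 2 * i]
                r1 = x[ci, ni, 2 * i + 1]
                for j in range(w2):
                    best = r0[2 * j]
                    which = 0
                    if r0[2 * j + 1] > best:
                        best = r0[2 * j + 1]
                        which = 1
                    if r1[2 * j] > best:
                        best = r1[2 * j]
                        which = 2
                    if r1[2 * j + 1] > best:
                        best = r1[2 * j + 1]
                        which = 3
                    out[ci, ni, i, j] = best
                    idx[ci, ni, i, j] = which
    return out, idx


@njit(cache=True)
def maxpool_backward(grad, idx, h, w):
    c, n, h2, w2 = grad.shape
    gx = np.zeros((c, n, h, w), dtype=F32)
    for ci in range(c):
        for ni in range(n):
            for i in range(h2):
                for j in range(w2):
                    which = idx[ci, ni, i, j]
                    gx[ci, ni, 2 * i + (which >> 1), 2 * j + (which & 1)] = grad[
                        ci, ni, i, j
                    ]
    return gx


@njit(cache=True)
def channel_pool(x):
    """Mean / max / argmax over the spatial axes: (C, N, H, W) -> 3 x (C, N)."""
    c, n, h, w = x.shape
    m = h * w
    xf = x.reshape(c, n, m)
    mean = np.empty((c, n), dtype=F32)
    mx = np.empty((c, n), dtype=F32)
    arg = np.empty((c, n), dtype=np.int64)
    for ci in range(c):
        for ni in range(n):
            row = xf[ci, ni]
            s = F32(0.0)
            best = row[0]
            bi = 0
            for i in range(m):
                v = row[i]
                s += v
                if v > best:
                    best = v
                    bi = i
            mean[ci, ni] = s / m
            mx[ci, ni] = best
            arg[ci, ni] = bi
    return mean, mx, arg


@njit(cache=True)
def channel_pool_scatter(dmax, arg, c, n, h, w):
    m = h * w
    out = np.zeros((c, n, m), dtype=F32)
    for ci in range(c):
        for ni in range(n):
            out[ci, ni, arg[ci, ni]] = dmax[ci, ni]
    return out.reshape(c, n, h, w)


@njit(cache=True)
def spatial_pool(x):
    """Mean / max / arg over channels: (C, N, H, W) -> (2, N, H, W) + arg."""
    c, n, h, w = x.shape
    s = np.empty((2, n, h, w), dtype=F32)
    arg = np.zeros((n, h, w), dtype=np.int16)
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                s[0, ni, i, j] = x[0, ni, i, j]
                s[1, ni, i, j] = x[0, ni, i, j]
    for ci in range(1, c):
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    v = x[ci, ni, i, j]
                    s[0, ni, i, j] += v
                    if v > s[1, ni, i, j]:
                        s[1, ni, i, j] = v
                        arg[ni, i, j] = ci
    inv = F32(1.0 / c)
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                s[0, ni, i, j] *= inv
    return s, arg


@njit(cache=True)
def spatial_attention_backward(grad, x, a, ds_mean, ds_max, arg):
    """dx = grad * a + ds_mean / C (broadcast) + scatter of ds_max at arg."""
    c, n, h, w = x.shape
    dx = np.empty_like(x)
    inv = F32(1.0 / c)
    for ci in range(c):
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    v = grad[ci, ni, i, j] * a[ni, i, j] + ds_mean[ni, i, j] * inv
                    if arg[ni, i, j] == ci:
                        v += ds_max[ni, i, j]
                    dx[ci, ni, i, j] = v
    return dx


@njit(cache=True)
def gate_mul_sum(grad, x):
    """(grad * x) summed over channels -> (N, H, W)  (spatial gate da)."""
    c, n, h, w = x.shape
    out = np.zeros((n, h, w), dtype=F32)
    for ci in range(c):
        for ni in range(n):
            for i in range(h):
                for j in range(w):
                    out[ni, i, j] += grad[ci, ni, i, j] * x[ci, ni, i, j]
    return out


@njit(cache=True)
def channel_gate_da(grad, x):
    """(grad * x) summed over the spatial axes -> (C, N)  (channel gate da)."""
    c, n, h, w = x.shape
    m = h * w
    gf = grad.reshape(c, n, m)
    xf = x.reshape(c, n, m)
    out = np.empty((c, n), dtype=F32)
    for ci in range(c):
        for ni in range(n):
            s = F32(0.0)
            for i in range(m):
                s += gf[ci, ni, i] * xf[ci, ni, i]
            out[ci, ni] = s
    return out


@njit(cache=True)
def channel_attention_backward(grad, a, dsa, dsm, arg):
    """dx = grad * a (per channel/sample) + dsa / (H*W) + scatter(dsm at arg)."""
    c, n, h, w = grad.shape
    m = h * w
    gf = grad.reshape(c, n, m)
    dx = np.empty((c, n, m), dtype=F32)
    for ci in range(c):
        for ni in range(n):
            g = a[ci, ni]
            add = dsa[ci, ni] / m
            for i in range(m):
                dx[ci, ni, i] = gf[ci, ni, i] * g + add
            dx[ci, ni, arg[ci, ni]] += dsm[ci, ni]
    return dx.reshape(c, n, h, w)


@njit(cache=True)
def bn_stats(x):
    """Per-channel mean and variance in one pass (sum / sum of squares)."""
    c = x.shape[0]
    m = x.size // c
    xf = x.reshape(c, m)
    mean = np.empty(c, dtype=F32)
    var = np.empty(c, dtype=F32)
    for ci in range(c):
        s = 0.0
        ss = 0.0
        for i in range(m):
            v = np.float64(xf[ci, i])
            s += v
            ss += v * v
        mu = s / m
        mean[ci] = mu
        var[ci] = max(ss / m - mu * mu, 0.0)
    return mean, var


@njit(cache=True)
def conv2_direct(s, w, bias, k):
    """Direct same-padding conv, 2 input channels -> 1 output map.

    s: (2, N, H, W); w: flat (2*k*k,) in (channel, di, dj) order.
    Cheaper than im2col for this tiny channel count (no cols buffer).
    """
    _, n, h, w_ = s.shape
    p = k // 2
    out = np.empty((1, n, h, w_), dtype=F32)
    for ni in range(n):
        for i in range(h):
            for j in range(w_):
                acc = bias
                for ci in range(2):
                    for di in range(k):
                        yy = i + di - p
                        if yy < 0 or yy >= h:
                            continue
                        base = (ci * k + di) * k
                        for dj in range(k):
                            xx = j + dj - p
                            if 0 <= xx < w_:
                                acc += w[base + dj] * s[ci, ni, yy, xx]
                out[0, ni, i, j] = acc
    return out


@njit(cache=True)
def conv2_direct_backward(dpre, s, w, k):
    """Gradients of conv2_direct: (dW flat, db, dS)."""
    _, n, h, w_ = s.shape
    p = k // 2
    dw = np.zeros(2 * k * k, dtype=F32)
    db = F32(0.0)
    ds = np.zeros_like(s)
    for ni in range(n):
        for i in range(h):
            for j in range(w_):
                g = dpre[0, ni, i, j]
                if g == 0.0:
                    continue
                db += g
                for ci in range(2):
                    for di in range(k):
                        yy = i + di - p
                        if yy < 0 or yy >= h:
                            continue
                        base = (ci * k + di) * k
                        for dj in range(k):
                            xx = j + dj - p
                            if 0 <= xx < w_:
                                dw[base + dj] += g * s[ci, ni, yy, xx]
                                ds[ci, ni, yy, xx] += g * w[base + dj]
    return dw, db, ds
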