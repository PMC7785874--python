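"""Differentiable NN primitives for volumetric (and planar) feature grids.

Layout convention: channels-last, ``(N, *spatial, C)`` with 1-3 spatial
axes.  Convolutions are stride-1 with symmetric "same" zero padding, the
only configuration the networks in this package use; pooling and nearest
upsampling work with per-axis integer factors so that anisotropic grids
(axial size collapsed to 1) are handled.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make


def _spatial_ndim(x: Tensor) -> int:
    return x.ndim - 2


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._prev:
        mask = x.data > 0

        def _bw(g, a=x):
            a.accumulate_grad(g * mask)
        out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    d = x.data
    y = np.empty_like(d)
    pos = d >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    y[~pos] = e / (1.0 + e)
    out = _make(y, (x,))
    if out._prev:
        def _bw(g, a=x, yv=y):
            a.accumulate_grad(g * yv * (1.0 - yv))
        out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _make(data, tuple(tensors))
    if out._prev:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g, ts=tuple(tensors)):
            parts = np.split(np.asarray(g), splits, axis=axis)
            for t, p in zip(ts, parts):
                if t.requires_grad or t._prev:
                    t.accumulate_grad(p)
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _offset_view(xp: np.ndarray, offset: tuple[int, ...], shape: tuple[int, ...]):
    """View of the padded array shifted by `offset`, spatial extent `shape`."""
    sl = [slice(None)]
    for o, s in zip(offset, shape):
        sl.append(slice(o, o + s))
    sl.append(slice(None))
    return xp[tuple(sl)]


def conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding correlation.

    ``x``: (N, *spatial, Cin); ``w``: (*kernel, Cin, Cout); ``b``: (Cout,).
    Implemented as one GEMM per kernel offset (shift-and-accumulate), which
    keeps peak memory at one activation volume instead of an im2col matrix.
    """
    nsp = _spatial_ndim(x)
    kshape = w.shape[:nsp]
    cin, cout = w.shape[nsp], w.shape[nsp + 1]
    if x.shape[-1] != cin:
        raise ValueError(f"conv: input has {x.shape[-1]} channels, kernel expects {cin}")
    spatial = x.shape[1:-1]
    pads = [(k // 2, k - 1 - k // 2) for k in kshape]
    if any(k % 2 == 0 for k in kshape):
        raise ValueError("conv: kernel sizes must be odd for symmetric padding")
    xp = np.pad(x.data, [(0, 0)] + pads + [(0, 0)])
    acc = np.zeros(x.shape[:-1] + (cout,), dtype=np.float32)
    offsets = list(np.ndindex(*kshape))
    for off in offsets:
        xv = _offset_view(xp, off, spatial)
        acc += np.matmul(xv, w.data[off])
    if b is not None:
        acc += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _make(acc, parents)
    if out._prev:
        def _bw(g, a=x, wt=w, bt=b, xpad=xp):
            g = np.asarray(g)
            if wt.requires_grad or wt._prev:
                dw = np.empty_like(wt.data)
                sp_axes = tuple(range(nsp + 1))
                for off in offsets:
                    xv = _offset_view(xpad, off, spatial)
                    dw[off] = np.tensordot(xv, g, axes=(sp_axes, sp_axes))
                wt.accumulate_grad(dw)
            if bt is not None and (bt.requires_grad or bt._prev):
                bt.accumulate_grad(g.sum(axis=tuple(range(g.ndim - 1))))
            if a.requires_grad or a._prev:
                dxp = np.zeros(xpad.shape, dtype=np.float32)
                for off in offsets:
                    dv = _offset_view(dxp, off, spatial)
                    dv += np.matmul(g, wt.data[off].T)
                sl = [slice(None)]
                for (p0, _), s in zip(pads, spatial):
                    sl.append(slice(p0, p0 + s))
                sl.append(slice(None))
                a.accumulate_grad(dxp[tuple(sl)])
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def _pool_reshape(x: np.ndarray, factors: tuple[int, ...]):
    """Reshape (N, *S, C) -> (N, *S/f, prod(f), C) gathering each window."""
    n, c = x.shape[0], x.shape[-1]
    spatial = x.shape[1:-1]
    shape = [n]
    for s, f in zip(spatial, factors):
        if s % f:
            raise ValueError(f"pool: size {s} not divisible by factor {f}")
        shape += [s // f, f]
    shape.append(c)
    xr = x.reshape(shape)
    nsp = len(spatial)
    perm = [0] + [1 + 2 * i for i in range(nsp)] + [2 + 2 * i for i in range(nsp)] + [xr.ndim - 1]
    xt = xr.transpose(perm)
    out_sp = tuple(s // f for s, f in zip(spatial, factors))
    return xt.reshape((n,) + out_sp + (int(np.prod(factors)), c))


def max_pool(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Max pooling by per-axis integer factors (each must divide the size)."""
    factors = tuple(int(f) for f in factors)
    if all(f == 1 for f in factors):
        return x
    win = _pool_reshape(x.data, factors)
    idx = win.argmax(axis=-2)
    y = np.take_along_axis(win, idx[..., None, :], axis=-2)[..., 0, :]
    out = _make(y, (x,))
    if out._prev:
        in_shape = x.shape

        def _bw(g, a=x):
            gwin = np.zeros(win.shape, dtype=np.float32)
            np.put_along_axis(gwin, idx[..., None, :], np.asarray(g)[..., None, :], axis=-2)
            # invert _pool_reshape
            n, c = in_shape[0], in_shape[-1]
            spatial = in_shape[1:-1]
            nsp = len(spatial)
            out_sp = tuple(s // f for s, f in zip(spatial, factors))
            gt = gwin.reshape((n,) + out_sp + factors + (c,))
            perm = [0]
            for i in range(nsp):
                perm += [1 + i, 1 + nsp + i]
            perm.append(gt.ndim - 1)
            a.accumulate_grad(gt.transpose(perm).reshape(in_shape))
        out._backward = _bw
    return out


def upsample_nearest(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    factors = tuple(int(f) for f in factors)
    if all(f == 1 for f in factors):
        return x
    y = x.data
    for ax, f in enumerate(factors, start=1):
        if f != 1:
            y = np.repeat(y, f, axis=ax)
    out = _make(y, (x,))
    if out._prev:
        in_shape = x.shape

        def _bw(g, a=x):
            g = np.asarray(g)
            n, c = in_shape[0], in_shape[-1]
            shape = [n]
            for s, f in zip(in_shape[1:-1], factors):
                shape += [s, f]
            shape.append(c)
            axes = tuple(2 + 2 * i for i in range(len(factors)))
            a.accumulate_grad(g.reshape(shape).sum(axis=axes))
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-3,
) -> Tensor:
    """Per-channel batch normalization over batch + spatial axes.

    In training mode batch statistics are used and the running estimates
    (plain arrays owned by the module) are updated in place; in eval mode
    the running estimates are used and receive no gradient.
    """
    red = tuple(range(x.ndim - 1))
    if training:
        mu = x.data.mean(axis=red)
        var = x.data.var(axis=red)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    y = xhat * gamma.data + beta.data
    out = _make(y.astype(np.float32), (x, gamma, beta))
    if out._prev:
        m = float(np.prod([x.shape[a] for a in red]))

        def _bw(g, a=x, gm=gamma, bt=beta):
            g = np.asarray(g)
            if gm.requires_grad or gm._prev:
                gm.accumulate_grad((g * xhat).sum(axis=red))
            if bt.requires_grad or bt._prev:
                bt.accumulate_grad(g.sum(axis=red))
            if a.requires_grad or a._prev:
                dxhat = g * gm.data
                if training:
                    dx = (
                        dxhat
                        - dxhat.mean(axis=red)
                        - xhat * (dxhat * xhat).mean(axis=red)
                    ) * ivar
                else:
                    dx = dxhat * ivar
                a.accumulate_grad(dx.astype(np.float32))
        out._backward = _bw
    return out
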