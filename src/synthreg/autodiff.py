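"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

The registration network, spatial transformer and losses are differentiable
programs over dense arrays; this module provides exactly the operator set
they need, each with a hand-written vector-Jacobian product:

* elementwise arithmetic with broadcasting, ``sum``/``mean``
* N-D "same"-padded convolution (stride 1 or 2) via im2col + BLAS
* LeakyReLU, channel concatenation, nearest 2x upsampling
* a differentiable warp (linear interpolation, zero fill) with gradients
  with respect to both the volume and the displacement
* separable linear resizing (a fixed linear map; adjoint by transposition)

Feature maps use the channel-first layout ``(C, *spatial)``; displacement
and velocity tensors in the differentiable path are ``(D, *spatial)``.
Every op is covered by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fields import _interp_matrix

__all__ = ["Tensor", "concat", "leaky_relu", "conv_nd", "upsample2x_nearest",
           "warp_cf", "compose_cf", "integrate_svf_cf", "resize_linear_cf",
           "grad_penalty"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=backward)

    def __pow__(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g_exp, self.data.shape)
            self._accumulate(grad.copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=backward
        )

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)


def concat(tensors, axis=0):
    """Concatenate tensors along ``axis`` (used for skip connections)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * np.where(mask, 1.0, slope))

    return Tensor(np.where(mask, x.data, slope * x.data), parents=(x,), backward=backward)


def conv_nd(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """N-D convolution, "same" padding, odd kernel, channel-first layout.

    ``x``: (C_in, *S); ``w``: (C_out, C_in, *k); ``b``: (C_out,).
    With stride 2, output position i corresponds to input position 2i, so
    even input sizes halve exactly.
    """
    ndim = x.data.ndim - 1
    kernel = w.data.shape[2:]
    pad = tuple(k // 2 for k in kernel)
    xp = np.pad(x.data, ((0, 0),) + tuple((p, p) for p in pad))
    win = sliding_window_view(xp, kernel, axis=tuple(range(1, ndim + 1)))
    win = win[(slice(None),) + (slice(None, None, stride),) * ndim]
    # sum over (C_in, *k): w axes 1..ndim+1, win axes 0 and ndim+1..2*ndim
    out = np.tensordot(
        w.data, win,
        axes=(list(range(1, ndim + 2)), [0] + list(range(ndim + 1, 2 * ndim + 1))),
    )
    out = out + b.data.reshape((-1,) + (1,) * ndim)
    out_spatial = out.shape[1:]

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=tuple(range(1, ndim + 1))))
        if w.requires_grad:
            # grad_w[co, ci, k] = sum_pos g[co, pos] * win[ci, pos, k]
            gw = np.tensordot(g, win, axes=(list(range(1, ndim + 1)), list(range(1, ndim + 1))))
            w._accumulate(gw)
        if x.requires_grad:
            # t[ci, *k, *pos] = sum_co w[co, ci, k] * g[co, pos]
            t = np.tensordot(w.data, g, axes=([0], [0]))
            gxp = np.zeros_like(xp)
            for offsets in itertools.product(*[range(k) for k in kernel]):
                sl = tuple(
                    slice(o, o + stride * n, stride)
                    for o, n in zip(offsets, out_spatial)
                )
                gxp[(slice(None),) + sl] += t[(slice(None),) + offsets]
            unpad = tuple(slice(p, xp.shape[i + 1] - p) for i, p in enumerate(pad))
            x._accumulate(gxp[(slice(None),) + unpad])

    return Tensor(out, parents=(x, w, b), backward=backward)


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of every spatial axis of (C, *S)."""
    ndim = x.data.ndim - 1
    out = x.data
    for axis in range(1, ndim + 1):
        out = np.repeat(out, 2, axis=axis)

    def backward(g):
        grad = g
        for axis in range(1, ndim + 1):
            shape = list(grad.shape)
            shape[axis] //= 2
            shape.insert(axis + 1, 2)
            grad = grad.reshape(shape).sum(axis=axis + 1)
        x._accumulate(grad)

    return Tensor(out, parents=(x,), backward=backward)


def warp_cf(vol: Tensor, u: Tensor) -> Tensor:
    """Differentiable warp: linear interpolation, zero fill outside the grid.

    ``vol``: (C, *S); ``u``: (D, *S) displacement in voxels. Output voxel k
    of each channel samples ``vol`` at ``k + u(:, k)``. Gradients flow to
    both the volume and the displacement.
    """
    ndim = u.data.shape[0]
    spatial = u.data.shape[1:]
    nvox = int(np.prod(spatial))
    bound = np.array(spatial).reshape((ndim,) + (1,) * ndim)
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in spatial], indexing="ij"), axis=0
    )
    pos = grid + u.data
    floor = np.floor(pos).astype(np.int64)
    frac = pos - floor

    channels = vol.data.shape[0]
    out = np.zeros((channels,) + spatial)
    corners = []  # cache per-corner data for the backward pass
    for offset in itertools.product((0, 1), repeat=ndim):
        idx = floor + np.array(offset).reshape((ndim,) + (1,) * ndim)
        inside = np.all((idx >= 0) & (idx < bound), axis=0)
        idx = np.clip(idx, 0, bound - 1)
        w1d = [frac[d] if offset[d] else 1.0 - frac[d] for d in range(ndim)]
        weight = np.ones(spatial)
        for wd in w1d:
            weight = weight * wd
        lin = np.ravel_multi_index(tuple(idx), spatial)
        vals = vol.data.reshape(channels, nvox)[:, lin.ravel()].reshape((channels,) + spatial)
        vals = vals * inside
        out += weight * vals
        corners.append((offset, inside, lin, w1d, weight, vals))

    def backward(g):
        if vol.requires_grad:
            gvol = np.zeros((nvox, channels))  # scatter on the leading axis
        gu = np.zeros_like(u.data) if u.requires_grad else None
        for offset, inside, lin, w1d, weight, vals in corners:
            if vol.requires_grad:
                contrib = (g * weight * inside).reshape(channels, nvox)
                np.add.at(gvol, lin.ravel(), contrib.T)
            if gu is not None:
                gv = (g * vals).sum(axis=0)  # sum over channels
                for d in range(ndim):
                    partial = np.ones(spatial)
                    for e in range(ndim):
                        if e != d:
                            partial = partial * w1d[e]
                    sign = 1.0 if offset[d] else -1.0
                    gu[d] += sign * partial * gv
        if vol.requires_grad:
            vol._accumulate(gvol.T.reshape(vol.data.shape))
        if gu is not None:
            u._accumulate(gu)

    return Tensor(out, parents=(vol, u), backward=backward)


def compose_cf(u_outer: Tensor, u_inner: Tensor) -> Tensor:
    """Displacement of ``(Id + u_outer) o (Id + u_inner)``, channel-first."""
    return u_inner + warp_cf(u_outer, u_inner)


def integrate_svf_cf(v: Tensor, steps: int = 5) -> Tensor:
    """Differentiable scaling-and-squaring integration of (D, *S) fields."""
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    u = v * (1.0 / 2**steps)
    for _ in range(steps):
        u = compose_cf(u, u)
    return u


def resize_linear_cf(x: Tensor, target_shape, value_scale=None) -> Tensor:
    """Separable linear resize of (C, *S) along the spatial axes.

    ``value_scale`` optionally multiplies channel ``i`` by a per-channel
    factor (used to convert displacements between grid units).
    """
    ndim = x.data.ndim - 1
    mats = [_interp_matrix(x.data.shape[1 + a], target_shape[a]) for a in range(ndim)]

    def apply(arr, transpose=False):
        out = arr
        for a in range(ndim):
            mat = mats[a].T if transpose else mats[a]
            out = np.moveaxis(
                np.tensordot(mat, np.moveaxis(out, a + 1, 0), axes=(1, 0)), 0, a + 1
            )
        return out

    scale = None
    if value_scale is not None:
        scale = np.asarray(value_scale, dtype=float).reshape((-1,) + (1,) * ndim)
    out = apply(x.data)
    if scale is not None:
        out = out * scale

    def backward(g):
        if scale is not None:
            g = g * scale
        x._accumulate(apply(g, transpose=True))

    return Tensor(out, parents=(x,), backward=backward)


def grad_penalty(u: Tensor) -> Tensor:
    """Smoothness penalty ``1/2 * mean |forward-difference gradient of u|^2``.

    Forward differences along each spatial axis with edge replication (the
    last slice's difference is zero); the mean runs over axes, components
    and voxels, so the penalty is resolution independent.
    """
    ndim = u.data.ndim - 1
    diffs = []
    for axis in range(1, ndim + 1):
        d = np.zeros_like(u.data)
        sl_hi = [slice(None)] * u.data.ndim
        sl_lo = [slice(None)] * u.data.ndim
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        d[tuple(sl_lo)] = u.data[tuple(sl_hi)] - u.data[tuple(sl_lo)]
        diffs.append(d)
    total = ndim * u.data.size
    value = 0.5 * sum(float(np.sum(d * d)) for d in diffs) / total

    def backward(g):
        gu = np.zeros_like(u.data)
        c = float(g) / total
        for axis, d in enumerate(diffs, start=1):
            sl_hi = [slice(None)] * u.data.ndim
            sl_lo = [slice(None)] * u.data.ndim
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            gu[tuple(sl_hi)] += c * d[tuple(sl_lo)]
            gu[tuple(sl_lo)] -= c * d[tuple(sl_lo)]
        u._accumulate(gu)

    return Tensor(value, parents=(u,), backward=backward)
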