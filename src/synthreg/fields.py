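"""Grid geometry, interpolation, and stationary-velocity-field (SVF) integration.

Conventions used throughout the package:

* Coordinates are 0-based voxel indices; spacing is one voxel per unit.
* Scalar volumes have shape ``(*spatial,)``; vector fields carry their
  components along a trailing axis, shape ``(*spatial, D)``, in index order
  (axis 0 slowest).
* Displacements and velocities are expressed in full-resolution voxel units,
  even when a field is stored on a reduced grid.
* Sampling outside the grid uses a fill value (default 0) rather than edge
  clamping, so anatomy reaching the volume edge is extrapolated with zeros.

A deformation is represented by its displacement ``u`` with
``phi = Id + u``; warping a volume moves voxel ``k`` to the value found at
``k + u(k)``.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "as_fraction",
    "lowres_shape",
    "sample_lowres_gaussian",
    "resize_linear",
    "upsample_field",
    "warp",
    "compose",
    "integrate_svf",
    "jacobian_determinant",
    "folding_fraction",
]


def as_fraction(r) -> Fraction:
    """Coerce a resolution factor to an exact rational.

    Accepts :class:`~fractions.Fraction`, ints, floats, or strings of the
    form ``"1:32"`` (the conventional notation for reduced resolutions).
    """
    if isinstance(r, Fraction):
        return r
    if isinstance(r, str):
        if ":" in r:
            num, den = r.split(":")
            return Fraction(int(num), int(den))
        return Fraction(r)
    if isinstance(r, int):
        return Fraction(r)
    # floats: snap to a nearby simple rational so ceil() is exact
    return Fraction(float(r)).limit_denominator(10**6)


def lowres_shape(shape: Sequence[int], r) -> tuple[int, ...]:
    """Reduced grid shape: each dimension multiplied by ``r``, rounded up."""
    r = as_fraction(r)
    if r <= 0 or r > 1:
        raise ValueError(f"resolution factor must satisfy 0 < r <= 1, got {r}")
    return tuple(int(math.ceil(d * r)) for d in shape)


def sample_lowres_gaussian(shape, r, sd, channels=1, rng=None):
    """Sample an i.i.d. Normal(0, sd^2) field on the reduced grid.

    Returns an array of shape ``lowres_shape(shape, r) + (channels,)``.
    """
    if any(int(d) <= 0 for d in shape):
        raise ValueError(f"shape must be positive, got {tuple(shape)}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    rng = np.random.default_rng(rng)
    low = lowres_shape(shape, r)
    return rng.normal(0.0, sd, size=low + (int(channels),)) if sd > 0 else np.zeros(
        low + (int(channels),)
    )


def _interp_matrix(old: int, new: int) -> np.ndarray:
    """Dense 1D linear-interpolation matrix mapping length ``old`` to ``new``.

    Endpoints map to endpoints (the output grid spans the input grid).
    """
    if old == 1:
        return np.ones((new, 1))
    pos = np.linspace(0.0, old - 1.0, new)
    lo = np.minimum(np.floor(pos).astype(int), old - 2)
    w = pos - lo
    mat = np.zeros((new, old))
    mat[np.arange(new), lo] += 1.0 - w
    mat[np.arange(new), lo + 1] += w
    return mat


def resize_linear(arr: np.ndarray, target_shape: Sequence[int], axes=None) -> np.ndarray:
    """Separable linear resize of ``arr`` along ``axes`` (default: all)."""
    arr = np.asarray(arr, dtype=float)
    if axes is None:
        axes = range(len(target_shape))
    out = arr
    for axis, new in zip(axes, target_shape):
        old = out.shape[axis]
        if new == old:
            continue
        mat = _interp_matrix(old, new)
        out = np.moveaxis(np.tensordot(mat, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def upsample_field(field, target_shape, scale_values: bool = False):
    """Linearly upsample a scalar or vector field to ``target_shape``.

    ``field`` is either ``(*spatial,)`` (scalar mode) or ``(*spatial, C)``
    with a trailing channel axis. In vector mode with ``scale_values`` set,
    component ``i`` is multiplied by the axis-``i`` zoom factor, converting
    a displacement expressed in source-grid voxels to target-grid voxels.
    """
    field = np.asarray(field, dtype=float)
    target_shape = tuple(int(t) for t in target_shape)
    ndim = len(target_shape)
    if field.ndim == ndim:
        has_channels = False
    elif field.ndim == ndim + 1:
        has_channels = True
    else:
        raise ValueError(
            f"field with {field.ndim} axes does not match target of {ndim} spatial axes"
        )
    src = field.shape[:ndim]
    if any(t < s for t, s in zip(target_shape, src)):
        raise ValueError(f"cannot shrink field from {src} to {target_shape}")
    out = resize_linear(field, target_shape, axes=range(ndim))
    if scale_values:
        if not has_channels or field.shape[-1] != ndim:
            raise ValueError("scale_values requires a vector field with D components")
        factors = np.array([t / s for t, s in zip(target_shape, src)])
        out = out * factors
    return out


def _check_displacement(u, spatial=None):
    u = np.asarray(u, dtype=float)
    if u.ndim < 2 or u.shape[-1] != u.ndim - 1:
        raise ValueError(
            f"displacement must have shape (*spatial, D); got {u.shape}"
        )
    if spatial is not None and u.shape[:-1] != tuple(spatial):
        raise ValueError(f"displacement spatial shape {u.shape[:-1]} != volume {tuple(spatial)}")
    return u


def warp(volume, u, interp: str = "linear", fill: float = 0.0):
    """Resample ``volume`` through the deformation ``phi = Id + u``.

    Output voxel ``k`` takes the interpolated value of ``volume`` at
    ``k + u(k)``. ``volume`` may carry a trailing channel axis. Positions
    outside the grid take the fill value; nearest mode never invents labels
    and preserves the input dtype.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {interp!r}")
    u = np.asarray(u, dtype=float)
    ndim = u.shape[-1]
    spatial = u.shape[:-1]
    u = _check_displacement(u)
    volume = np.asarray(volume)
    if volume.shape[:ndim] != spatial or volume.ndim not in (ndim, ndim + 1):
        raise ValueError(
            f"volume shape {volume.shape} incompatible with displacement {u.shape}"
        )
    has_channels = volume.ndim == ndim + 1
    bound = np.array(spatial)
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in spatial], indexing="ij"), axis=-1
    )
    pos = grid + u

    if interp == "nearest":
        idx = np.rint(pos).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < bound), axis=-1)
        idx = np.clip(idx, 0, bound - 1)
        out = volume[tuple(np.moveaxis(idx, -1, 0))].copy()
        out[~inside] = np.asarray(fill).astype(out.dtype) if not has_channels else fill
        return out

    floor = np.floor(pos).astype(np.int64)
    frac = pos - floor
    out_shape = spatial + ((volume.shape[-1],) if has_channels else ())
    out = np.zeros(out_shape, dtype=float)
    vol = volume.astype(float, copy=False)
    for offset in itertools.product((0, 1), repeat=ndim):
        idx = floor + np.array(offset)
        weight = np.ones(spatial)
        for d in range(ndim):
            weight = weight * (frac[..., d] if offset[d] else 1.0 - frac[..., d])
        inside = np.all((idx >= 0) & (idx < bound), axis=-1)
        idx = np.clip(idx, 0, bound - 1)
        vals = vol[tuple(np.moveaxis(idx, -1, 0))]
        if has_channels:
            vals = np.where(inside[..., None], vals, fill)
            out += weight[..., None] * vals
        else:
            vals = np.where(inside, vals, fill)
            out += weight * vals
    return out


def compose(u_outer, u_inner):
    """Displacement of ``(Id + u_outer) o (Id + u_inner)``.

    ``u = u_inner + u_outer(Id + u_inner)``, with zero fill outside the grid.
    """
    u_outer = _check_displacement(u_outer)
    u_inner = _check_displacement(u_inner)
    if u_outer.shape != u_inner.shape:
        raise ValueError(f"shape mismatch: {u_outer.shape} vs {u_inner.shape}")
    return u_inner + warp(u_outer, u_inner, interp="linear", fill=0.0)


def integrate_svf(v, steps: int = 5):
    """Integrate a stationary velocity field by scaling and squaring.

    The field is halved ``steps`` times to a small displacement
    ``u0 = v / 2**steps`` which is then composed with itself ``steps``
    times. ``steps=0`` returns ``v`` unchanged (interpreted directly as a
    displacement).
    """
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    v = _check_displacement(v)
    u = v / float(2**steps)
    for _ in range(steps):
        u = compose(u, u)
    return u


def jacobian_determinant(u):
    """Per-voxel determinant of the Jacobian of ``phi = Id + u``.

    Central differences in the interior, one-sided at the boundary. Equals
    1 everywhere for ``u = 0``.
    """
    u = _check_displacement(u)
    ndim = u.shape[-1]
    spatial = u.shape[:-1]
    jac = np.empty(spatial + (ndim, ndim))
    for comp in range(ndim):
        grads = np.gradient(u[..., comp], axis=tuple(range(ndim)))
        if ndim == 1:
            grads = [grads]
        for axis in range(ndim):
            jac[..., comp, axis] = grads[axis] + (1.0 if comp == axis else 0.0)
    return np.linalg.det(jac)


def folding_fraction(u) -> float:
    """Fraction of voxels where det(J_phi) <= 0 (local orientation reversal)."""
    det = jacobian_determinant(u)
    return float(np.mean(det <= 0.0))
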