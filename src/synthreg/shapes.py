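"""Synthesis of random geometric label maps and of training label-map pairs.

The generative model draws, for each of ``J`` labels, a smooth noise image
(standard-normal voxels sampled on a coarse grid and linearly upsampled),
warps it by a random diffeomorphism obtained by integrating a smooth random
stationary velocity field, and assigns each voxel the label whose warped
noise image is largest there. Labels are 1..J with no background; argmax
covers every voxel by construction. The same velocity-field machinery
deforms label maps to create moving/fixed training pairs.

All velocity magnitudes are expressed in full-resolution voxel units: a
field sampled with standard deviation ``sd`` on a coarse grid is upsampled
without value rescaling, so ``sd`` bounds the displacement rate on the full
grid regardless of the sampling resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .fields import (
    as_fraction,
    integrate_svf,
    sample_lowres_gaussian,
    upsample_field,
    warp,
)

__all__ = [
    "ShapeGenConfig",
    "WarpGenConfig",
    "synth_shape_labels",
    "sample_random_svf",
    "deform_labels",
    "make_label_pair",
]

#: resolutions combined additively when both maps of a pair derive from one
#: source map and a more complex deformation is needed
MULTI_SCALE_RESOLUTIONS = (Fraction(1, 8), Fraction(1, 16), Fraction(1, 32))


@dataclass
class ShapeGenConfig:
    """Parameters of the random-shape label-map generator."""

    shape: tuple = (160, 160, 192)
    num_labels: int = 26          # J
    r_p: Fraction = Fraction(1, 32)   # sampling resolution of noise and warps
    b_p: float = 100.0            # max SD of the per-label warp SVF (voxels)
    background: bool = False      # relabel the lowest-mean channel as 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.r_p = as_fraction(self.r_p)
        if self.num_labels < 1:
            raise ValueError(f"num_labels must be >= 1, got {self.num_labels}")
        if self.b_p < 0:
            raise ValueError(f"b_p must be >= 0, got {self.b_p}")


@dataclass
class WarpGenConfig:
    """Parameters of the random deformations applied to label-map pairs."""

    r_v: tuple = (Fraction(1, 16),)   # one resolution, or several to combine
    b_v: float = 3.0                  # max SVF standard deviation (voxels)

    def __post_init__(self):
        if isinstance(self.r_v, (str, Fraction, int, float)):
            self.r_v = (self.r_v,)
        self.r_v = tuple(as_fraction(r) for r in self.r_v)
        if not self.r_v:
            raise ValueError("r_v must contain at least one resolution")
        if self.b_v < 0:
            raise ValueError(f"b_v must be >= 0, got {self.b_v}")

    @classmethod
    def multi_scale(cls, b_v: float = 3.0) -> "WarpGenConfig":
        """Configuration for single-source pairs (several resolutions summed)."""
        return cls(r_v=MULTI_SCALE_RESOLUTIONS, b_v=b_v)


def sample_random_svf(shape, r, sd_max, multi_scale: bool = False, rng=None):
    """Draw a smooth random SVF at full resolution.

    Single scale: draw ``sigma ~ U(0, sd_max)``, sample i.i.d.
    ``Normal(0, sigma^2)`` voxels at resolution ``r`` and upsample linearly.
    Multi scale: ``r`` is a sequence of resolutions; an independent field is
    drawn per resolution (independent sigma each) and the upsampled fields
    are summed.
    """
    if sd_max < 0:
        raise ValueError(f"sd_max must be >= 0, got {sd_max}")
    rng = np.random.default_rng(rng)
    shape = tuple(int(s) for s in shape)
    ndim = len(shape)
    resolutions = tuple(r) if multi_scale else (r,)
    if not resolutions:
        raise ValueError("empty resolution set")
    total = np.zeros(shape + (ndim,))
    for res in resolutions:
        sigma = rng.uniform(0.0, sd_max) if sd_max > 0 else 0.0
        low = sample_lowres_gaussian(shape, res, sigma, channels=ndim, rng=rng)
        total += upsample_field(low, shape, scale_values=False)
    return total


def synth_shape_labels(cfg: ShapeGenConfig, rng=None) -> np.ndarray:
    """Synthesize a label map of random geometric shapes.

    For each label j = 1..J: sample a smooth standard-normal noise image at
    resolution ``r_p``, warp it by the diffeomorphism integrated from a
    random SVF (SD drawn uniformly from [0, b_p]), and take the voxelwise
    argmax over labels (ties broken by the lowest label index).
    """
    rng = np.random.default_rng(rng)
    shape = cfg.shape
    stack = np.empty((cfg.num_labels,) + shape)
    for j in range(cfg.num_labels):
        noise = sample_lowres_gaussian(shape, cfg.r_p, 1.0, channels=1, rng=rng)
        image = upsample_field(noise[..., 0], shape)
        if cfg.b_p > 0:
            v = sample_random_svf(shape, cfg.r_p, cfg.b_p, rng=rng)
            image = warp(image, integrate_svf(v), interp="linear", fill=0.0)
        stack[j] = image
    labels = np.argmax(stack, axis=0).astype(np.int32) + 1
    if cfg.background:
        means = [stack[j][labels == j + 1].mean() if np.any(labels == j + 1) else np.inf
                 for j in range(cfg.num_labels)]
        labels[labels == int(np.argmin(means)) + 1] = 0
    return labels


def deform_labels(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Deform a label map by the diffeomorphism integrated from SVF ``v``.

    Nearest-neighbour interpolation with background fill 0, so the output
    label vocabulary is a subset of the input's plus 0.
    """
    u = integrate_svf(np.asarray(v, dtype=float))
    return warp(np.asarray(s), u, interp="nearest", fill=0)


def make_label_pair(
    mode: str,
    source,
    wcfg: WarpGenConfig | None = None,
    rng=None,
    return_warps: bool = False,
):
    """Draw a (moving, fixed) label-map pair for training.

    ``mode='shapes'``: ``source`` is a single map, deformed twice with
    independent multi-scale SVFs — both maps share one topology so an exact
    correspondence exists. ``mode='anatomy'``: ``source`` is a pool of >= 2
    maps; two distinct members are each deformed with an independent
    single-scale SVF, capturing inter-subject variability.
    """
    rng = np.random.default_rng(rng)
    if mode == "shapes":
        if wcfg is None:
            wcfg = WarpGenConfig.multi_scale()
        s = np.asarray(source)
        resolutions = wcfg.r_v if len(wcfg.r_v) > 1 else MULTI_SCALE_RESOLUTIONS
        v_m = sample_random_svf(s.shape, resolutions, wcfg.b_v, multi_scale=True, rng=rng)
        v_f = sample_random_svf(s.shape, resolutions, wcfg.b_v, multi_scale=True, rng=rng)
        s_m, s_f = deform_labels(s, v_m), deform_labels(s, v_f)
    elif mode == "anatomy":
        pool = list(source)
        if len(pool) < 2:
            raise ValueError("anatomy mode requires a pool of at least 2 label maps")
        if wcfg is None:
            wcfg = WarpGenConfig()
        i, k = rng.choice(len(pool), size=2, replace=False)
        s_a, s_b = np.asarray(pool[i]), np.asarray(pool[k])
        v_m = sample_random_svf(s_a.shape, wcfg.r_v[0], wcfg.b_v, rng=rng)
        v_f = sample_random_svf(s_b.shape, wcfg.r_v[0], wcfg.b_v, rng=rng)
        s_m, s_f = deform_labels(s_a, v_m), deform_labels(s_b, v_f)
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    if return_warps:
        return s_m, s_f, integrate_svf(v_m), integrate_svf(v_f)
    return s_m, s_f
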