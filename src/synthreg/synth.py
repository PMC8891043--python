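"""Gray-scale image synthesis from label maps, with randomized contrast.

Given a label map, an image of arbitrary contrast is produced by a fixed
chain of four stages:

1. **GMM sampling** — each label receives a random mean and standard
   deviation, and every voxel of that label is an independent normal draw.
2. **Anisotropic blur** — separable Gaussian smoothing with an independent
   kernel width per axis, imitating partial-volume effects and varying
   acquisition resolution.
3. **Bias field** — a smooth multiplicative intensity inhomogeneity,
   simulated by exponentiating a smooth zero-mean random field.
4. **Normalization and gamma** — min-max rescaling to [0, 1] followed by
   global exponentiation ``m^exp(gamma)``, altering contrast but not
   geometry.

Calling the chain twice on the two maps of a training pair yields images
whose contrasts are fully decorrelated, which is what forces the downstream
network to rely on geometry alone. A smoothed random lookup-table transform
is also provided for contrast augmentation of acquired images.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .fields import as_fraction, sample_lowres_gaussian, upsample_field

__all__ = [
    "SynthConfig",
    "GmmDraw",
    "sample_gmm_image",
    "blur_anisotropic",
    "apply_bias",
    "normalize_gamma",
    "synth_image",
    "lut_contrast_augment",
]


@dataclass
class SynthConfig:
    """Bounds of the randomized image-synthesis stages (intensities are
    arbitrary units; spatial measures are voxels)."""

    a_mu: float = 25.0        # intensity-mean bounds per label
    b_mu: float = 225.0
    a_sigma: float = 5.0      # intensity-SD bounds per label
    b_sigma: float = 25.0
    b_K: float = 1.0          # max blur SD per axis
    r_B: Fraction = Fraction(1, 40)   # bias-field sampling resolution
    b_B: float = 0.3          # max bias-field SD (log scale)
    sigma_gamma: float = 0.25  # SD of the global gamma exponent

    def __post_init__(self):
        self.r_B = as_fraction(self.r_B)
        if not self.a_mu < self.b_mu:
            raise ValueError("a_mu must be < b_mu")
        if not self.a_sigma < self.b_sigma:
            raise ValueError("a_sigma must be < b_sigma")
        for name in ("a_mu", "a_sigma", "b_K", "b_B", "sigma_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GmmDraw:
    """The per-label intensity parameters drawn for one synthetic image."""

    labels: np.ndarray
    means: np.ndarray
    sds: np.ndarray


def sample_gmm_image(s: np.ndarray, cfg: SynthConfig, rng=None):
    """Per-label Gaussian intensities: label j's voxels are i.i.d.
    Normal(mu_j, sigma_j^2) with mu_j ~ U(a_mu, b_mu), sigma_j ~ U(a_sigma,
    b_sigma). Returns the image and the drawn parameters."""
    rng = np.random.default_rng(rng)
    s = np.asarray(s)
    labels = np.unique(s)
    means = rng.uniform(cfg.a_mu, cfg.b_mu, size=labels.size)
    sds = rng.uniform(cfg.a_sigma, cfg.b_sigma, size=labels.size)
    noise = rng.standard_normal(s.shape)
    mean_map = np.zeros(s.shape)
    sd_map = np.zeros(s.shape)
    for lab, mu, sd in zip(labels, means, sds):
        mask = s == lab
        mean_map[mask] = mu
        sd_map[mask] = sd
    return mean_map + sd_map * noise, GmmDraw(labels, means, sds)


def blur_anisotropic(img: np.ndarray, cfg: SynthConfig, rng=None) -> np.ndarray:
    """Separable Gaussian blur with an independent SD ~ U(0, b_K) per axis.

    Kernels are truncated at 3 SD and normalized to unit sum; the reflect
    boundary rule avoids darkening image edges.
    """
    if cfg.b_K < 0:
        raise ValueError("b_K must be non-negative")
    rng = np.random.default_rng(rng)
    out = np.asarray(img, dtype=float)
    for axis in range(out.ndim):
        sigma = rng.uniform(0.0, cfg.b_K)
        if sigma > 0:
            out = gaussian_filter1d(out, sigma, axis=axis, mode="reflect", truncate=3.0)
    return out


def apply_bias(img: np.ndarray, cfg: SynthConfig, rng=None) -> np.ndarray:
    """Multiply by a smooth positive bias field.

    A zero-mean normal field with SD ~ U(0, b_B) is sampled at resolution
    ``r_B``, linearly upsampled, and exponentiated, yielding a strictly
    positive multiplicative inhomogeneity.
    """
    rng = np.random.default_rng(rng)
    img = np.asarray(img, dtype=float)
    sigma = rng.uniform(0.0, cfg.b_B)
    low = sample_lowres_gaussian(img.shape, cfg.r_B, sigma, channels=1, rng=rng)
    bias = upsample_field(low[..., 0], img.shape)
    return img * np.exp(bias)


def normalize_gamma(img: np.ndarray, cfg: SynthConfig, rng=None) -> np.ndarray:
    """Min-max normalize to [0, 1], then exponentiate globally.

    With gamma ~ Normal(0, sigma_gamma^2) the output is ``m^exp(gamma)``;
    the endpoints 0 and 1 are fixed points of the power law. A constant
    image maps to zeros (the min-max is degenerate).
    """
    rng = np.random.default_rng(rng)
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    normed = (img - lo) / (hi - lo)
    gamma = rng.normal(0.0, cfg.sigma_gamma) if cfg.sigma_gamma > 0 else 0.0
    return normed ** np.exp(gamma)


def synth_image(s: np.ndarray, cfg: SynthConfig | None = None, rng=None):
    """Full synthesis chain: GMM -> blur -> bias -> min-max/gamma.

    Returns an image in [0, 1] plus the GMM draw. Each call uses fresh
    randomness, so two calls on the maps of a pair give images with
    independent contrasts.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(rng)
    img, draw = sample_gmm_image(s, cfg, rng)
    img = blur_anisotropic(img, cfg, rng)
    img = apply_bias(img, cfg, rng)
    img = normalize_gamma(img, cfg, rng)
    return img, draw


def lut_contrast_augment(img: np.ndarray, sigma_L: float = 64.0, rng=None) -> np.ndarray:
    """Remap intensities through a smoothed random lookup table.

    A 256-entry table of U(0, 255) draws is smoothed with a 1D Gaussian of
    SD ``sigma_L`` (reflect padding) and applied by linear interpolation to
    the input (expected in [0, 1], internally scaled to the 0..255 range);
    the result is rescaled back to [0, 1]. Voxels with equal inputs map to
    equal outputs: the transform changes contrast only.
    """
    if sigma_L <= 0:
        raise ValueError(f"sigma_L must be positive, got {sigma_L}")
    rng = np.random.default_rng(rng)
    lut = rng.uniform(0.0, 255.0, size=256)
    lut = gaussian_filter1d(lut, sigma_L, mode="reflect", truncate=3.0)
    img = np.asarray(img, dtype=float)
    mapped = np.interp(np.clip(img, 0.0, 1.0) * 255.0, np.arange(256), lut)
    return mapped / 255.0
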