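"""The registration network h_theta(m, f).

A convolutional U-Net maps the concatenated moving/fixed image pair to a
stationary velocity field at half resolution. The encoder has 4 blocks
(stride-2 convolution + LeakyReLU 0.2), the decoder 3 blocks (stride-1
convolution + LeakyReLU, nearest 2x upsampling, skip concatenation with
the matching encoder output). Three further stride-1 convolutions refine
the half-resolution features before a final convolution with one filter
per spatial dimension emits the velocity field. The final layer is
initialized to zeros so an untrained network predicts the identity warp.

Integrating the velocity field (scaling and squaring, 5 steps by default)
and linearly upsampling the displacement to full resolution — with values
doubled to convert half-grid to full-grid voxel units — yields the dense
warp ``phi = Id + u``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .fields import warp

__all__ = ["RegNetConfig", "RegNet", "predict_warp", "register_pair"]


@dataclass
class RegNetConfig:
    ndim: int = 3
    width: int = 256          # filters per convolution (n)
    encoder_levels: int = 4
    leaky_slope: float = 0.2
    kernel: int = 3
    integ_steps: int = 5

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {self.ndim}")
        if self.width < self.ndim:
            raise ValueError("width must be at least ndim")


class RegNet:
    """U-Net registration model with explicit numpy parameters."""

    def __init__(self, cfg: RegNetConfig, rng=None):
        self.cfg = cfg
        rng = np.random.default_rng(rng)
        self.params: dict[str, ad.Tensor] = {}
        n, d, k = cfg.width, cfg.ndim, cfg.kernel
        c_in = 2
        for i in range(cfg.encoder_levels):
            self._add_conv(f"enc{i + 1}", c_in, n, rng)
            c_in = n
        for i in range(3):
            self._add_conv(f"dec{i + 1}", c_in, n, rng)
            c_in = 2 * n  # after skip concatenation
        for i in range(3):
            self._add_conv(f"ref{i + 1}", c_in, n, rng)
            c_in = n
        self._add_conv("svf", c_in, d, rng, zero=True)

    def _add_conv(self, name, c_in, c_out, rng, zero=False):
        k = self.cfg.kernel
        shape = (c_out, c_in) + (k,) * self.cfg.ndim
        if zero:
            weight = np.zeros(shape)
        else:
            fan_in = c_in * k**self.cfg.ndim
            weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self.params[f"{name}.w"] = ad.Tensor(weight, requires_grad=True)
        self.params[f"{name}.b"] = ad.Tensor(np.zeros(c_out), requires_grad=True)

    # -- forward ---------------------------------------------------------
    def _conv(self, name, x, stride=1, activate=True):
        out = ad.conv_nd(x, self.params[f"{name}.w"], self.params[f"{name}.b"], stride=stride)
        return ad.leaky_relu(out, self.cfg.leaky_slope) if activate else out

    def _validate(self, m, f):
        m, f = np.asarray(m, float), np.asarray(f, float)
        if m.shape != f.shape:
            raise ValueError(f"moving/fixed shape mismatch: {m.shape} vs {f.shape}")
        if m.ndim != self.cfg.ndim:
            raise ValueError(f"expected {self.cfg.ndim}-D inputs, got {m.ndim}-D")
        div = 2**self.cfg.encoder_levels
        if any(s % div for s in m.shape):
            raise ValueError(f"input shape {m.shape} must be divisible by {div}")
        return m, f

    def forward(self, m, f, features: dict | None = None) -> ad.Tensor:
        """Predict the half-resolution velocity field for an image pair.

        ``features``, if given, collects named intermediate layer outputs
        (used by the contrast-invariance probe).
        """
        m, f = self._validate(m, f)
        x = ad.Tensor(np.stack([m, f], axis=0))
        if features is not None:
            features["input"] = x
        skips = []
        for i in range(self.cfg.encoder_levels):
            x = self._conv(f"enc{i + 1}", x, stride=2)
            skips.append(x)
            if features is not None:
                features[f"enc{i + 1}"] = x
        for i in range(3):
            x = self._conv(f"dec{i + 1}", x)
            x = ad.upsample2x_nearest(x)
            x = ad.concat([x, skips[-(i + 2)]], axis=0)
            if features is not None:
                features[f"dec{i + 1}"] = x
        for i in range(3):
            x = self._conv(f"ref{i + 1}", x)
            if features is not None:
                features[f"ref{i + 1}"] = x
        v = self._conv("svf", x, activate=False)
        if features is not None:
            features["svf"] = v
        return v

    def predict_displacement(self, v: ad.Tensor) -> ad.Tensor:
        """Integrate a half-resolution SVF and upsample to the full warp."""
        full_shape = tuple(2 * s for s in v.data.shape[1:])
        u_half = ad.integrate_svf_cf(v, steps=self.cfg.integ_steps)
        return ad.resize_linear_cf(u_half, full_shape, value_scale=[2.0] * self.cfg.ndim)

    # -- persistence -----------------------------------------------------
    def save(self, path):
        arrays = {k: t.data for k, t in self.params.items()}
        arrays["__ndim"] = np.array(self.cfg.ndim)
        arrays["__width"] = np.array(self.cfg.width)
        arrays["__integ_steps"] = np.array(self.cfg.integ_steps)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "RegNet":
        with np.load(path) as data:
            cfg = RegNetConfig(
                ndim=int(data["__ndim"]),
                width=int(data["__width"]),
                integ_steps=int(data["__integ_steps"]),
            )
            net = cls(cfg, rng=0)
            for key in net.params:
                net.params[key].data = data[key].copy()
        return net

    def num_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())


def predict_warp(net: RegNet, m, f):
    """Velocity field and full-resolution displacement for an image pair.

    Returns ``(v, u)`` as numpy arrays: ``v`` with shape
    ``(*spatial/2, D)`` and ``u`` with shape ``(*spatial, D)`` (channel-last,
    full-resolution voxel units).
    """
    v_t = net.forward(m, f)
    u_t = net.predict_displacement(v_t)
    v = np.moveaxis(v_t.data, 0, -1)
    u = np.moveaxis(u_t.data, 0, -1)
    return v, u


def register_pair(net: RegNet, m, f, interp: str = "linear"):
    """Warp the moving image onto the fixed image. Returns (moved, u)."""
    _, u = predict_warp(net, m, f)
    return warp(np.asarray(m), u, interp=interp, fill=0.0), u
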