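"""Deterministic miniature fixtures so every test is self-contained.

All fixtures are generated programmatically from a seed through the shapes
and synthesis modules with scaled-down geometry; nothing is loaded from
disk. The ``pairset`` kind provides a registration problem with a known
ground-truth warp: the fixed map is the moving map pushed through the
integrated field, so propagating the moving labels through ``u_true``
reproduces the fixed labels exactly.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .fields import integrate_svf, warp
from .shapes import ShapeGenConfig, sample_random_svf, synth_shape_labels
from .synth import SynthConfig, synth_image

__all__ = ["make_fixture"]

_KINDS = ("shapes2d", "shapes3d", "pairset")


def make_fixture(kind: str, seed: int = 0) -> dict:
    """Build a tiny, fully deterministic fixture.

    ``shapes2d``: 64^2 label map with 8 labels. ``shapes3d``: 16^3 map with
    4 labels. ``pairset``: 2D maps (s_m, s_f), images (m, f) and the exact
    ground-truth displacement ``u_true`` with ``s_f = s_m o (Id + u_true)``.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if kind == "shapes2d":
        cfg = ShapeGenConfig(shape=(64, 64), num_labels=8)
        return {"labels": synth_shape_labels(cfg, rng), "config": cfg}
    if kind == "shapes3d":
        cfg = ShapeGenConfig(shape=(16, 16, 16), num_labels=4, r_p=Fraction(1, 8), b_p=20.0)
        return {"labels": synth_shape_labels(cfg, rng), "config": cfg}

    cfg = ShapeGenConfig(shape=(64, 64), num_labels=8)
    s_m = synth_shape_labels(cfg, rng)
    v = sample_random_svf(cfg.shape, Fraction(1, 16), 3.0, rng=rng)
    u_true = integrate_svf(v)
    s_f = warp(s_m, u_true, interp="nearest", fill=0)
    synth_cfg = SynthConfig()
    m, _ = synth_image(s_m, synth_cfg, rng)
    f, _ = synth_image(s_f, synth_cfg, rng)
    return {"s_m": s_m, "s_f": s_f, "m": m, "f": f, "u_true": u_true, "v_true": v,
            "config": cfg}
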