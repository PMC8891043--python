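"""NIfTI volume I/O, run configuration, and seeding helpers.

Volumes are stored as NIfTI-1. 2D data are written with a singleton third
axis (and read back squeezed); displacement/velocity fields carry their
vector components along a trailing (fourth) dimension. Round trips
preserve voxel data bit-exactly and the affine header verbatim. Label maps
must be integer-typed on disk; reading a floating-point file as labels is
an explicit error, never a silent cast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction

import nibabel as nib
import numpy as np
import yaml

from .fields import as_fraction
from .shapes import ShapeGenConfig, WarpGenConfig
from .synth import SynthConfig
from .train import TrainConfig

__all__ = ["read_volume", "write_volume", "read_field", "write_field",
           "RunConfig", "load_config", "save_config", "spawn_rngs"]


def write_volume(x: np.ndarray, path, affine=None) -> None:
    """Write a 2D/3D scalar or label volume as NIfTI-1."""
    x = np.asarray(x)
    if x.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D volume, got shape {x.shape}")
    data = x[..., None] if x.ndim == 2 else x
    if affine is None:
        affine = np.eye(4)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path, kind: str = "image"):
    """Read a NIfTI volume; ``kind`` is ``"image"`` or ``"labels"``.

    Returns ``(data, affine)``. A singleton third axis is squeezed so 2D
    volumes round-trip to their original shape.
    """
    if kind not in ("image", "labels"):
        raise ValueError(f"kind must be 'image' or 'labels', got {kind!r}")
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if kind == "labels" and not np.issubdtype(dtype, np.integer):
        raise TypeError(
            f"label volume {path} has non-integer on-disk datatype {dtype}; "
            "refusing to cast silently"
        )
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (2, 3) and not (data.ndim == 4 and data.shape[2] == 1):
        if data.ndim != 3:
            raise ValueError(f"unsupported payload with {data.ndim} axes in {path}")
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data, img.affine


def write_field(u: np.ndarray, path, affine=None) -> None:
    """Write a displacement/velocity field, components on a trailing axis."""
    u = np.asarray(u, dtype=np.float64)
    ndim = u.shape[-1]
    if u.ndim != ndim + 1 or ndim not in (2, 3):
        raise ValueError(f"expected (*spatial, D) field with D in (2, 3); got {u.shape}")
    data = u[:, :, None, :] if ndim == 2 else u
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_field(path):
    """Read a vector field written by :func:`write_field`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D field file, got {data.ndim} axes in {path}")
    if data.shape[2] == 1 and data.shape[3] == 2:
        data = data[:, :, 0, :]
    return data, img.affine


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Flat run configuration: every generator hyperparameter by name.

    Resolution factors are written as ``"1:32"`` strings in YAML and parsed
    to exact rationals. Defaults are the reference values.
    """

    mode: str = "shapes"
    seed: int = 0
    shape: tuple = (160, 160, 192)
    iterations: int = 400_000
    width: int = 256
    num_labels: int = 26      # J
    lam: float = 1.0
    r_p: str = "1:32"
    b_p: float = 100.0
    a_mu: float = 25.0
    b_mu: float = 225.0
    a_sigma: float = 5.0
    b_sigma: float = 25.0
    r_B: str = "1:40"
    b_B: float = 0.3
    b_K: float = 1.0
    sigma_gamma: float = 0.25
    r_v: tuple = ("1:16",)
    b_v: float = 3.0
    integ_steps: int = 5
    lr: float = 1e-4
    lr_fallback: float = 1e-5
    pool_size: int = 100

    def to_train_config(self) -> TrainConfig:
        r_v = self.r_v if isinstance(self.r_v, (list, tuple)) else (self.r_v,)
        return TrainConfig(
            mode=self.mode,
            shape=tuple(self.shape),
            width=self.width,
            iterations=self.iterations,
            lam=self.lam,
            lr=self.lr,
            lr_fallback=self.lr_fallback,
            seed=self.seed,
            pool_size=self.pool_size,
            integ_steps=self.integ_steps,
            shape_cfg=ShapeGenConfig(
                shape=tuple(self.shape), num_labels=self.num_labels,
                r_p=as_fraction(self.r_p), b_p=self.b_p),
            warp_cfg=WarpGenConfig(
                r_v=tuple(as_fraction(r) for r in r_v), b_v=self.b_v),
            synth_cfg=SynthConfig(
                a_mu=self.a_mu, b_mu=self.b_mu, a_sigma=self.a_sigma,
                b_sigma=self.b_sigma, b_K=self.b_K, r_B=as_fraction(self.r_B),
                b_B=self.b_B, sigma_gamma=self.sigma_gamma),
        )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are named in the error."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    if "shape" in raw:
        raw["shape"] = tuple(raw["shape"])
    if "r_v" in raw:
        r_v = raw["r_v"]
        raw["r_v"] = tuple(r_v) if isinstance(r_v, (list, tuple)) else (r_v,)
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["shape"] = list(cfg.shape)
    data["r_v"] = list(cfg.r_v)
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def spawn_rngs(seed: int, count: int):
    """Fan one global seed out to independent generator streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]
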