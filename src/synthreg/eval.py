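"""Registration accuracy and contrast-invariance metrics.

Accuracy is measured by propagating the moving label map through the
predicted warp (nearest-neighbour interpolation, so no labels are invented)
and comparing to the fixed map: hard Dice overlap per label, mean symmetric
surface distance (MSD) between label contours in voxels, and deformation
regularity statistics (folding fraction and mean Jacobian determinant).

The feature-RMSD probe quantifies contrast invariance: the same geometry is
re-rendered under several contrasts, one network layer's output is compared
across renderings by a per-channel RMS difference normalized by the
reference channel's RMS, and averaged over contrasts and channels. Lower
values mean the layer's response depends on geometry, not appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

from .fields import folding_fraction, jacobian_determinant, warp
from .model import RegNet, predict_warp

__all__ = ["EvalReport", "hard_dice", "msd", "feature_rmsd", "evaluate_pair"]


@dataclass
class EvalReport:
    """Per-label overlap/distance scores plus deformation statistics."""

    dice: dict = field(default_factory=dict)
    msd: dict = field(default_factory=dict)
    folding_fraction: float = 0.0
    mean_jacobian: float = 1.0

    def mean_dice(self) -> float:
        return float(np.mean(list(self.dice.values())))

    def to_dict(self) -> dict:
        return {
            "dice": {str(k): v for k, v in self.dice.items()},
            "msd": {str(k): v for k, v in self.msd.items()},
            "folding_fraction": self.folding_fraction,
            "mean_jacobian": self.mean_jacobian,
        }


def hard_dice(a: np.ndarray, b: np.ndarray, label) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|) of one label's supports.

    Defined as 1 if the label is absent from both maps, 0 if absent from
    exactly one.
    """
    mask_a = np.asarray(a) == label
    mask_b = np.asarray(b) == label
    total = mask_a.sum() + mask_b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(mask_a, mask_b).sum() / total)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Face-connected boundary voxels (volume-edge voxels included)."""
    structure = generate_binary_structure(mask.ndim, 1)
    eroded = binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def msd(a: np.ndarray, b: np.ndarray, label) -> float:
    """Mean symmetric surface distance between one label's contours, voxels.

    Boundary voxels are label voxels with a face-adjacent non-label
    neighbour (or on the volume edge). The metric averages the two directed
    mean nearest-boundary Euclidean distances, so it is symmetric in its
    arguments.
    """
    mask_a = np.asarray(a) == label
    mask_b = np.asarray(b) == label
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"label {label!r} empty in one of the maps; MSD undefined")
    bnd_a, bnd_b = _boundary(mask_a), _boundary(mask_b)
    dist_to_b = distance_transform_edt(~bnd_b)
    dist_to_a = distance_transform_edt(~bnd_a)
    return float(0.5 * (dist_to_b[bnd_a].mean() + dist_to_a[bnd_b].mean()))


def feature_rmsd(net: RegNet, layer: str, pairs) -> float:
    """Variability of one layer's response across re-contrasted inputs.

    ``pairs`` is a sequence of (moving, fixed) images depicting the same
    geometry under different moving contrasts, with a constant fixed image.
    The first pair is the reference. For each other pair and each feature
    channel, the RMS difference to the reference over space is divided by
    the reference channel's spatial RMS; the result is averaged over
    contrasts and channels. Zero for a perfectly contrast-invariant layer.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("feature_rmsd needs at least two contrast pairs")
    outputs = []
    for m, f in pairs:
        features: dict = {}
        net.forward(m, f, features=features)
        if layer not in features:
            raise ValueError(f"unknown layer {layer!r}; have {sorted(features)}")
        outputs.append(features[layer].data)
    reference = outputs[0]
    channels = reference.shape[0]
    spatial_axes = tuple(range(1, reference.ndim))
    ref_rms = np.sqrt(np.mean(reference**2, axis=spatial_axes))
    scores = []
    for other in outputs[1:]:
        rmsd = np.sqrt(np.mean((other - reference) ** 2, axis=spatial_axes))
        scores.append(rmsd / (ref_rms + 1e-12))
    return float(np.mean(scores))


def evaluate_pair(net: RegNet, m, f, s_m, s_f, labels) -> EvalReport:
    """Register one pair and report per-label Dice/MSD plus warp statistics.

    Pure: neither the inputs nor the model are modified.
    """
    _, u = predict_warp(net, m, f)
    moved = warp(np.asarray(s_m), u, interp="nearest", fill=0)
    report = EvalReport()
    for lab in labels:
        report.dice[lab] = hard_dice(moved, s_f, lab)
        try:
            report.msd[lab] = msd(moved, s_f, lab)
        except ValueError:
            report.msd[lab] = float("nan")
    report.folding_fraction = folding_fraction(u)
    report.mean_jacobian = float(np.mean(jacobian_determinant(u)))
    return report
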