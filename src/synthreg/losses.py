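"""Contrast-agnostic soft Dice, smoothness regularizer, and total objective.

The dissimilarity term never sees image intensities: the moving label map's
one-hot channels are warped with linear interpolation (soft probabilities,
differentiable in the displacement) and compared to the fixed one-hot map
with a soft Dice score averaged over labels,

    L_dis = -(2/J) * sum_j  |warped(s_m^j) . s_f^j| / |warped(s_m^j) + s_f^j|,

which is therefore invariant under any intensity transform of the images —
the formal statement of contrast agnosticism. The regularizer is
``1/2 * mean |grad u|^2`` on the displacement, and the total objective is
``L_dis + lambda * L_reg``.

The public functions accept plain numpy arrays and return floats; the
training loop calls the tensor-valued ``*_t`` variants on autodiff tensors
to obtain gradients. Both routes share one implementation.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "DICE_EPS",
    "one_hot",
    "soft_dice_loss",
    "soft_dice_loss_t",
    "grad_loss",
    "grad_loss_t",
    "total_loss",
    "supervised_mse_loss",
]

#: guard added to the Dice denominator so labels absent from both maps
#: contribute 0 rather than 0/0
DICE_EPS = 1e-5


def one_hot(s: np.ndarray, labels) -> np.ndarray:
    """Indicator channels for each entry of ``labels``, shape (*spatial, J).

    Voxels whose label is not listed carry zero mass in every channel, which
    restricts the loss to the listed labels.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("label list must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in {labels}")
    s = np.asarray(s)
    return np.stack([(s == lab).astype(float) for lab in labels], axis=-1)


def soft_dice_loss_t(onehot_m: np.ndarray, u: ad.Tensor, onehot_f: np.ndarray) -> ad.Tensor:
    """Tensor-valued soft Dice of warped moving vs fixed one-hot channels.

    ``onehot_m``/``onehot_f`` are channel-first arrays (J, *spatial); ``u``
    is a (D, *spatial) displacement tensor. Range (-1, 0]; -1 at perfect
    overlap of all included labels (up to the denominator guard).
    """
    ndim = u.data.shape[0]
    spatial_axes = tuple(range(1, ndim + 1))
    num_labels = onehot_m.shape[0]
    warped = ad.warp_cf(ad.Tensor(onehot_m), u)
    fixed = ad.Tensor(onehot_f)
    intersection = (warped * fixed).sum(axis=spatial_axes)
    union = warped.sum(axis=spatial_axes) + fixed.sum(axis=spatial_axes) + DICE_EPS
    return (intersection / union).sum() * (-2.0 / num_labels)


def soft_dice_loss(s_m: np.ndarray, u: np.ndarray, s_f: np.ndarray, labels) -> float:
    """Soft Dice loss between label maps, warping ``s_m`` by ``u``.

    ``u`` is channel-last (*spatial, D); ``labels`` selects the channels
    entering the loss.
    """
    oh_m = np.moveaxis(one_hot(s_m, labels), -1, 0)
    oh_f = np.moveaxis(one_hot(s_f, labels), -1, 0)
    u_t = ad.Tensor(np.moveaxis(np.asarray(u, float), -1, 0))
    return float(soft_dice_loss_t(oh_m, u_t, oh_f).data)


def grad_loss_t(u: ad.Tensor) -> ad.Tensor:
    """Tensor-valued smoothness penalty on a (D, *spatial) displacement."""
    return ad.grad_penalty(u)


def grad_loss(u: np.ndarray) -> float:
    """``1/2 * mean`` of squared forward-difference gradients of ``u``.

    ``u`` is channel-last (*spatial, D). Zero iff ``u`` is constant;
    homogeneous of degree 2.
    """
    u = np.asarray(u, float)
    return float(grad_loss_t(ad.Tensor(np.moveaxis(u, -1, 0))).data)


def total_loss(s_m, s_f, u, lam: float, labels) -> float:
    """Soft Dice plus ``lam`` times the smoothness penalty."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return soft_dice_loss(s_m, u, s_f, labels) + lam * grad_loss(u)


def supervised_mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared componentwise difference between two fields.

    Used for supervised training against the synthesized velocity field
    (compared at half resolution) or the net displacement (full resolution).
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return float(np.mean((pred - truth) ** 2))


def supervised_mse_loss_t(pred: ad.Tensor, truth: np.ndarray) -> ad.Tensor:
    """Tensor-valued MSE against a fixed ground-truth field."""
    truth = np.asarray(truth, float)
    if pred.data.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {truth.shape}")
    diff = pred - ad.Tensor(truth)
    return (diff * diff).mean()
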