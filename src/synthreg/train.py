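"""Training loop binding the generator, the network and the loss.

Every iteration synthesizes a fresh registration problem: a pair of label
maps (from random shapes, or from a pool of anatomical segmentations), a
pair of images with independent random contrasts, a predicted warp, and a
contrast-agnostic loss. Batch size is one pair; optimization is Adam with
an initial learning rate of 1e-4, dropped to 1e-5 once if divergence is
detected.

Modes
-----
``shapes``    single synthetic shape map deformed twice; soft Dice loss on
              all J labels (no acquired data of any kind).
``anatomy``   two distinct label maps from a user pool, each deformed once;
              soft Dice on a chosen label subset.
``sup_svf`` / ``sup_def``
              supervised variants: the fixed map is the moving map deformed
              by a known velocity field, and the network regresses that
              field (at half resolution) or the net displacement (at full
              resolution) with an MSE loss.
``hybrid``    acquired-image pairs whose network inputs are remapped with
              smoothed random lookup tables while the loss sees the
              un-augmented pair (label Dice by default; a pluggable MSE
              image similarity is provided).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .eval import hard_dice
from .fields import integrate_svf, resize_linear, warp
from .losses import grad_loss_t, one_hot, soft_dice_loss_t, supervised_mse_loss_t
from .model import RegNet, RegNetConfig, predict_warp
from .shapes import (
    MULTI_SCALE_RESOLUTIONS,
    ShapeGenConfig,
    WarpGenConfig,
    deform_labels,
    make_label_pair,
    sample_random_svf,
    synth_shape_labels,
)
from .synth import SynthConfig, lut_contrast_augment, synth_image

__all__ = ["TrainConfig", "TrainState", "Adam", "training_step", "train",
           "small_2d_shapes_config"]

MODES = ("shapes", "anatomy", "hybrid", "sup_svf", "sup_def")


@dataclass
class TrainConfig:
    """Full training configuration; defaults are the reference 3D setup."""

    mode: str = "shapes"
    shape: tuple = (160, 160, 192)
    width: int = 256
    iterations: int = 400_000
    lam: float = 1.0              # regularization weight
    lr: float = 1e-4
    lr_fallback: float = 1e-5
    seed: int = 0
    labels: tuple | None = None   # labels in the loss (None: all present)
    pool_size: int = 100          # synthetic shape maps to pre-generate
    integ_steps: int = 5
    shape_cfg: ShapeGenConfig | None = None
    warp_cfg: WarpGenConfig | None = None
    synth_cfg: SynthConfig = dc_field(default_factory=SynthConfig)
    val_interval: int = 1000
    val_pairs: int = 10
    checkpoint_interval: int | None = None
    flip_augment: bool = True     # joint axis flips (anatomy/hybrid only)
    similarity: str = "dice"      # hybrid loss: "dice" or "mse"
    sigma_L: float = 64.0         # hybrid LUT smoothing kernel SD

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.shape = tuple(int(s) for s in self.shape)
        if self.shape_cfg is None:
            self.shape_cfg = ShapeGenConfig(shape=self.shape)
        if self.warp_cfg is None:
            single_source = self.mode in ("shapes", "sup_svf", "sup_def")
            self.warp_cfg = (
                WarpGenConfig.multi_scale() if single_source else WarpGenConfig()
            )


def small_2d_shapes_config(iterations: int = 2000, seed: int = 0, **kwargs) -> TrainConfig:
    """The scaled-down 2D study configuration: 64^2 grid, width 16, J = 8.

    Generator magnitudes keep their reference values; only the grid, the
    network width and the label count are reduced so training completes in
    minutes on one CPU.
    """
    defaults = dict(
        mode="shapes",
        shape=(64, 64),
        width=16,
        iterations=iterations,
        seed=seed,
        shape_cfg=ShapeGenConfig(shape=(64, 64), num_labels=8),
        pool_size=100,
    )
    defaults.update(kwargs)
    return TrainConfig(**defaults)


class Adam:
    """First-order adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, tensor in self.params.items():
            g = tensor.grad
            if g is None:
                continue
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainState:
    net: RegNet
    optimizer: Adam
    rng: np.random.Generator
    iteration: int = 0
    loss_history: list = dc_field(default_factory=list)
    val_history: list = dc_field(default_factory=list)
    diverged: bool = False
    pool: list = dc_field(default_factory=list)
    val_set: list = dc_field(default_factory=list)
    loss_labels: tuple = ()
    last_sample: dict = dc_field(default_factory=dict)


def init_state(cfg: TrainConfig, pool: Sequence | None = None) -> TrainState:
    """Build network, optimizer and (for shapes modes) the shape-map pool.

    One global seed fans out to independent streams for initialization,
    pool generation, the training loop, and validation, so runs replay
    bit-exactly from (config, seed).
    """
    seq = np.random.SeedSequence(cfg.seed)
    init_s, pool_s, train_s, val_s = seq.spawn(4)
    net = RegNet(
        RegNetConfig(ndim=len(cfg.shape), width=cfg.width, integ_steps=cfg.integ_steps),
        rng=np.random.default_rng(init_s),
    )
    state = TrainState(
        net=net,
        optimizer=Adam(net.params, cfg.lr),
        rng=np.random.default_rng(train_s),
    )
    if cfg.mode in ("shapes", "sup_svf", "sup_def"):
        pool_rng = np.random.default_rng(pool_s)
        state.pool = [synth_shape_labels(cfg.shape_cfg, pool_rng)
                      for _ in range(cfg.pool_size)]
        state.loss_labels = tuple(range(1, cfg.shape_cfg.num_labels + 1))
    else:
        if pool is None or len(pool) < 2:
            raise ValueError(f"{cfg.mode} mode requires a pool of at least 2 entries")
        state.pool = list(pool)
        if cfg.labels is not None:
            state.loss_labels = tuple(cfg.labels)
        else:
            first = state.pool[0][1] if cfg.mode == "hybrid" else state.pool[0]
            labs = np.unique(np.asarray(first))
            state.loss_labels = tuple(int(l) for l in labs if l != 0)
    if cfg.labels is not None:
        state.loss_labels = tuple(cfg.labels)
    # fixed held-out synthetic pairs for validation
    val_rng = np.random.default_rng(val_s)
    for _ in range(cfg.val_pairs):
        state.val_set.append(_sample_pair(state, cfg, val_rng))
    return state


def _joint_flip(arrays, rng):
    """Flip all arrays jointly along each axis with probability 1/2."""
    ndim = arrays[0].ndim
    for axis in range(ndim):
        if rng.random() < 0.5:
            arrays = [np.flip(a, axis=axis) for a in arrays]
    return [np.ascontiguousarray(a) for a in arrays]


def _sample_pair(state: TrainState, cfg: TrainConfig, rng) -> dict:
    """Draw one training sample: label maps, images, and any supervision."""
    sample: dict = {}
    if cfg.mode == "shapes":
        s = state.pool[rng.integers(len(state.pool))]
        s_m, s_f = make_label_pair("shapes", s, cfg.warp_cfg, rng)
    elif cfg.mode in ("sup_svf", "sup_def"):
        # moving map undeformed: the sampled field is then exactly the truth
        s_m = state.pool[rng.integers(len(state.pool))]
        v_true = sample_random_svf(
            cfg.shape, cfg.warp_cfg.r_v if len(cfg.warp_cfg.r_v) > 1
            else MULTI_SCALE_RESOLUTIONS,
            cfg.warp_cfg.b_v, multi_scale=True, rng=rng)
        u_true = integrate_svf(v_true, cfg.integ_steps)
        s_f = warp(s_m, u_true, interp="nearest", fill=0)
        sample["v_true"] = v_true
        sample["u_true"] = u_true
    elif cfg.mode == "anatomy":
        s_m, s_f = make_label_pair("anatomy", state.pool, cfg.warp_cfg, rng)
        if cfg.flip_augment:
            s_m, s_f = _joint_flip([s_m, s_f], rng)
    elif cfg.mode == "hybrid":
        i, k = rng.choice(len(state.pool), size=2, replace=False)
        (img_m, s_m), (img_f, s_f) = state.pool[i], state.pool[k]
        if cfg.flip_augment:
            img_m, s_m, img_f, s_f = _joint_flip([img_m, s_m, img_f, s_f], rng)
        sample.update(m_clean=img_m, f_clean=img_f)
        sample.update(
            m=lut_contrast_augment(img_m, cfg.sigma_L, rng),
            f=lut_contrast_augment(img_f, cfg.sigma_L, rng),
            s_m=s_m, s_f=s_f)
        return sample
    m, _ = synth_image(s_m, cfg.synth_cfg, rng)
    f, _ = synth_image(s_f, cfg.synth_cfg, rng)
    sample.update(s_m=s_m, s_f=s_f, m=m, f=f)
    return sample


def _loss_tensor(state: TrainState, cfg: TrainConfig, sample: dict) -> ad.Tensor:
    net = state.net
    v_t = net.forward(sample["m"], sample["f"])
    if cfg.mode == "sup_svf":
        half = tuple(s // 2 for s in cfg.shape)
        # truth resampled to the half grid, values converted to half-grid units
        v_half = resize_linear(sample["v_true"], half, axes=range(len(half))) * 0.5
        return supervised_mse_loss_t(v_t, np.moveaxis(v_half, -1, 0))
    u_t = net.predict_displacement(v_t)
    if cfg.mode == "sup_def":
        return supervised_mse_loss_t(u_t, np.moveaxis(sample["u_true"], -1, 0))
    if cfg.mode == "hybrid" and cfg.similarity == "mse":
        moved = ad.warp_cf(ad.Tensor(sample["m_clean"][None]), u_t)
        diff = moved - ad.Tensor(sample["f_clean"][None])
        return (diff * diff).mean() + grad_loss_t(u_t) * cfg.lam
    oh_m = np.moveaxis(one_hot(sample["s_m"], state.loss_labels), -1, 0)
    oh_f = np.moveaxis(one_hot(sample["s_f"], state.loss_labels), -1, 0)
    dice = soft_dice_loss_t(oh_m, u_t, oh_f)
    return dice + grad_loss_t(u_t) * cfg.lam


def training_step(state: TrainState, cfg: TrainConfig) -> TrainState:
    """One generator -> network -> loss -> Adam update cycle."""
    sample = _sample_pair(state, cfg, state.rng)
    state.last_sample = sample
    loss_t = _loss_tensor(state, cfg, sample)
    loss = float(loss_t.data)
    loss_t.backward()
    state.optimizer.step()
    state.loss_history.append(loss)
    state.iteration += 1
    _check_divergence(state, cfg)
    return state


def _check_divergence(state: TrainState, cfg: TrainConfig):
    """Non-finite loss, or a sustained median increase of the loss over
    500-step blocks, triggers a one-time drop to the fallback rate."""
    if state.diverged:
        return
    hist = state.loss_history
    bad = not np.isfinite(hist[-1])
    if not bad and len(hist) >= 1000 and state.iteration % 500 == 0:
        recent = float(np.median(hist[-500:]))
        previous = float(np.median(hist[-1000:-500]))
        bad = recent > previous + 0.2
    if bad:
        state.diverged = True
        state.optimizer.lr = cfg.lr_fallback


def validate(state: TrainState, cfg: TrainConfig):
    """Mean hard Dice over the fixed held-out pairs, and identity baseline."""
    scores, identity = [], []
    for sample in state.val_set:
        _, u = predict_warp(state.net, sample["m"], sample["f"])
        moved = warp(sample["s_m"], u, interp="nearest", fill=0)
        for lab in state.loss_labels:
            scores.append(hard_dice(moved, sample["s_f"], lab))
            identity.append(hard_dice(sample["s_m"], sample["s_f"], lab))
    return float(np.mean(scores)), float(np.mean(identity))


def train(cfg: TrainConfig, pool: Sequence | None = None, out_dir=None) -> TrainState:
    """Run the full loop; optionally log to CSV and checkpoint under out_dir."""
    state = init_state(cfg, pool)
    writer = log_file = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        log_file = open(os.path.join(out_dir, "log.csv"), "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(["step", "loss", "lr", "val_dice", "val_dice_identity"])
    try:
        for _ in range(cfg.iterations):
            training_step(state, cfg)
            row = [state.iteration, state.loss_history[-1], state.optimizer.lr, "", ""]
            if state.iteration % cfg.val_interval == 0 or state.iteration == cfg.iterations:
                dice, ident = validate(state, cfg)
                state.val_history.append((state.iteration, dice, ident))
                row[3:] = [dice, ident]
            if writer is not None:
                writer.writerow(row)
            if (out_dir is not None and cfg.checkpoint_interval
                    and state.iteration % cfg.checkpoint_interval == 0):
                state.net.save(os.path.join(out_dir, f"checkpoint_{state.iteration}.npz"))
        if out_dir is not None:
            state.net.save(os.path.join(out_dir, "checkpoint_final.npz"))
    finally:
        if log_file is not None:
            log_file.close()
    return state
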