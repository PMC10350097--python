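"""Training and ensemble inference for direct tract segmentation.

The model maps the 6 order-2 SH coefficient channels of a b0-normalized
scan to per-voxel, per-tract probabilities.  Training draws a fresh
q-space subset every iteration (subset augmentation), projects it onto
the SH basis, samples a 3D patch and takes one Adam step on the soft
Dice loss; the learning rate is halved whenever the validation loss
fails to improve for a configurable number of epochs.  Inference runs
the model on n different measurement subsets and averages the
probability maps voxel-wise; the per-subset members are kept because
their disagreement is the basis of the uncertainty statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .gradients import DWISeries
from .sh import fit_sh, n_coefficients
from .subsets import SubsetSpec, make_test_subsets
from .unet import Adam, UNet3D

__all__ = [
    "ModelConfig",
    "EnsemblePrediction",
    "build_model",
    "soft_dice_loss",
    "train",
    "sliding_window_predict",
    "ensemble_predict",
    "binarize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    ``patch_shape`` must be divisible by 2**depth.  ``in_channels`` is
    tied to the SH order: (order+1)(order+2)/2, i.e. 6 at order 2.
    Defaults mirror a full-scale run (96³ patches, 41 tract channels,
    lr 1e-4, batch 1); tests and phantom studies scale them down.
    """

    patch_shape: tuple[int, int, int] = (96, 96, 96)
    sh_order: int = 2
    out_labels: int = 41
    depth: int = 2
    base_width: int = 8
    learning_rate: float = 1e-4
    lr_halve_patience: int = 1
    batch_size: int = 1
    epochs: int = 10
    iters_per_epoch: int = 100
    fg_patch_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        for s in self.patch_shape:
            if s % 2**self.depth:
                raise ValueError(
                    f"patch size {s} not divisible by 2^depth={2**self.depth}"
                )

    @property
    def in_channels(self) -> int:
        return n_coefficients(self.sh_order)


@dataclass
class EnsemblePrediction:
    """n per-subset probability maps y_k and their voxel-wise mean ȳ."""

    members: list  # list of (x, y, z, out_labels) arrays in [0, 1]
    subsets: list  # the SubsetSpec used for each member
    mean: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        stack = np.stack(self.members)
        if stack.min() < -1e-6 or stack.max() > 1 + 1e-6:
            raise ValueError("member probabilities outside [0, 1]")
        computed = stack.mean(axis=0)
        if self.mean is None:
            self.mean = computed
        elif not np.allclose(self.mean, computed, atol=1e-6):
            raise ValueError("stored mean disagrees with members")

    @property
    def n(self) -> int:
        return len(self.members)


def build_model(config: ModelConfig) -> UNet3D:
    """Instantiate the encoder-decoder with deterministic initialization."""
    return UNet3D(
        in_ch=config.in_channels,
        out_ch=config.out_labels,
        depth=config.depth,
        base_width=config.base_width,
        seed=config.seed,
    )


def soft_dice_loss(pred: np.ndarray, target: np.ndarray,
                   eps: float = 1e-6) -> float:
    """1 − soft Dice, averaged over label channels (last axis)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    ax = tuple(range(pred.ndim - 1))
    inter = (pred * target).sum(axis=ax)
    denom = pred.sum(axis=ax) + target.sum(axis=ax)
    return float(np.mean(1.0 - (2.0 * inter + eps) / (denom + eps)))


def _soft_dice_grad(pred: np.ndarray, target: np.ndarray,
                    eps: float = 1e-6) -> np.ndarray:
    """dLoss/dpred for :func:`soft_dice_loss` (channels last)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    ax = tuple(range(pred.ndim - 1))
    inter = (pred * target).sum(axis=ax)
    denom = pred.sum(axis=ax) + target.sum(axis=ax)
    n_lab = pred.shape[-1]
    # d/dp of -(2I+e)/(S+e): -(2t(S+e) - (2I+e)) / (S+e)^2
    num = 2.0 * target * (denom + eps) - (2.0 * inter + eps)
    return (-num / (denom + eps) ** 2 / n_lab).astype(np.float32)


def _sample_patch_origin(shape: Sequence[int], patch: Sequence[int],
                         labels: np.ndarray, rng: np.random.Generator,
                         fg_fraction: float) -> tuple[int, int, int]:
    """Random patch origin; with probability fg_fraction centered on a
    random foreground voxel (standard practice for sparse labels)."""
    max_org = [max(s - p, 0) for s, p in zip(shape, patch)]
    fg = np.argwhere(labels.any(axis=-1))
    if fg.size and rng.random() < fg_fraction:
        center = fg[rng.integers(len(fg))]
        org = [int(np.clip(c - p // 2, 0, m))
               for c, p, m in zip(center, patch, max_org)]
        return tuple(org)
    return tuple(int(rng.integers(m + 1)) for m in max_org)


def _project_patch(dwi: DWISeries, subset: SubsetSpec, origin, patch_shape,
                   order: int, reg_lambda: float = 0.0) -> np.ndarray:
    """SH-project one spatial patch of the subset's measurements;
    returns channels-first (n_coef, *patch_shape) float32."""
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
    idx = np.asarray(subset.indices, dtype=int)
    signals = dwi.data[sl + (idx,)].astype(np.float64)
    coeffs = fit_sh(signals, dwi.gtab.bvecs[idx], order=order,
                    reg_lambda=reg_lambda)
    return np.moveaxis(coeffs, -1, 0).astype(np.float32)


def train(
    model: UNet3D,
    train_cases: Sequence[tuple[DWISeries, np.ndarray]],
    val_cases: Sequence[tuple[DWISeries, np.ndarray]],
    config: ModelConfig,
    sampler: Iterator[SubsetSpec],
) -> tuple[UNet3D, pd.DataFrame]:
    """Dice-loss training with per-iteration q-space subset augmentation.

    ``train_cases`` / ``val_cases`` are (b0-normalized DWISeries, label
    volume) pairs, labels boolean of shape grid + (out_labels,).  Every
    iteration draws one subset from ``sampler``, projects a random patch
    of one training case onto the SH basis and takes one Adam step on
    the soft Dice loss.  The validation loss (full volumes, one subset
    fixed per case for comparability across epochs) drives the
    halve-on-plateau learning-rate schedule.  Returns the model and a
    per-epoch log (train/val loss, learning rate).
    """
    if not train_cases or not val_cases:
        raise ValueError("need at least one training and one validation case")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    # fixed validation subsets, one per case
    val_subsets = [
        make_test_subsets(dwi.gtab, k=6, n=1,
                          rng_seed=int(rng.integers(2**31)))[0]
        for dwi, _ in val_cases
    ]
    best_val = np.inf
    stall = 0
    rows = []
    for epoch in range(config.epochs):
        train_losses = []
        for _ in range(config.iters_per_epoch):
            model.zero_grad()
            case_i = int(rng.integers(len(train_cases)))
            dwi, labels = train_cases[case_i]
            subset = next(sampler)
            origin = _sample_patch_origin(
                dwi.shape, config.patch_shape, labels, rng,
                config.fg_patch_fraction,
            )
            x = _project_patch(dwi, subset, origin, config.patch_shape,
                               config.sh_order)
            sl = tuple(slice(o, o + p)
                       for o, p in zip(origin, config.patch_shape))
            target = labels[sl].astype(np.float32)
            prob = model.forward(x)  # (L, *patch)
            prob_cl = np.moveaxis(prob, 0, -1)
            loss = soft_dice_loss(prob_cl, target)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            grad = _soft_dice_grad(prob_cl, target)
            model.backward(np.moveaxis(grad, -1, 0))
            opt.step()
            train_losses.append(loss)
        val_loss = _validation_loss(model, val_cases, val_subsets, config)
        rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
            "lr": opt.lr,
        })
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_halve_patience:
                opt.lr *= 0.5
                stall = 0
    return model, pd.DataFrame(rows)


def _validation_loss(model, val_cases, val_subsets, config) -> float:
    losses = []
    for (dwi, labels), subset in zip(val_cases, val_subsets):
        x = _project_patch(dwi, subset, (0, 0, 0), dwi.shape, config.sh_order)
        prob = sliding_window_predict(model, x, config.patch_shape)
        losses.append(
            soft_dice_loss(np.moveaxis(prob, 0, -1),
                           labels.astype(np.float32))
        )
    return float(np.mean(losses))


def _tile_starts(size: int, patch: int, step: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)
    return starts


def sliding_window_predict(model: UNet3D, volume: np.ndarray,
                           patch_shape: Sequence[int],
                           overlap: float = 0.5) -> np.ndarray:
    """Whole-volume prediction by tiling with overlapping patches.

    ``volume`` is channels-first (C, X, Y, Z).  Overlapping patch
    predictions are averaged; a volume smaller than the patch in any
    axis is padded reflectively and the output cropped back.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    patch = tuple(int(p) for p in patch_shape)
    spatial = volume.shape[1:]
    pad = [(0, max(p - s, 0)) for s, p in zip(spatial, patch)]
    padded = np.pad(volume, [(0, 0)] + pad, mode="reflect") \
        if any(p[1] for p in pad) else volume
    pshape = padded.shape[1:]
    steps = [max(int(round(p * (1.0 - overlap))), 1) for p in patch]
    out = np.zeros((model.out_ch,) + pshape, dtype=np.float64)
    count = np.zeros(pshape, dtype=np.float64)
    for ox in _tile_starts(pshape[0], patch[0], steps[0]):
        for oy in _tile_starts(pshape[1], patch[1], steps[1]):
            for oz in _tile_starts(pshape[2], patch[2], steps[2]):
                sl = (slice(ox, ox + patch[0]), slice(oy, oy + patch[1]),
                      slice(oz, oz + patch[2]))
                out[(slice(None),) + sl] += model.forward(padded[(slice(None),) + sl])
                count[sl] += 1.0
    out /= count
    crop = tuple(slice(0, s) for s in spatial)
    return out[(slice(None),) + crop].astype(np.float32)


def ensemble_predict(
    model: UNet3D,
    dwi: DWISeries,
    config: ModelConfig,
    k: int = 6,
    n: int = 10,
    rng_seed: int = 0,
    disjoint: bool = False,
    reg_lambda: float = 0.0,
) -> EnsemblePrediction:
    """Predict with n measurement subsets and average voxel-wise.

    ``dwi`` must already be b0-normalized.  Each member is the
    sliding-window prediction from the SH projection of one subset;
    the mean over members is the final segmentation probability map.
    ``reg_lambda`` enables the Laplace–Beltrami-regularized SH fit,
    required when k is below the coefficient count (e.g. 3-measurement
    subsets at order 2).
    """
    if n < 1:
        raise ValueError("need n ≥ 1 subsets")
    subsets = make_test_subsets(dwi.gtab, k=k, n=n, rng_seed=rng_seed,
                                disjoint=disjoint)
    members = []
    for spec in subsets:
        x = _project_patch(dwi, spec, (0, 0, 0), dwi.shape, config.sh_order,
                           reg_lambda=reg_lambda)
        prob = sliding_window_predict(model, x, config.patch_shape)
        members.append(np.moveaxis(prob, 0, -1))  # back to channels-last
    return EnsemblePrediction(members=members, subsets=subsets)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-label mask: probability ≥ threshold."""
    prob = np.asarray(prob)
    if prob.min() < -1e-6 or prob.max() > 1 + 1e-6:
        raise ValueError("probabilities outside [0, 1]")
    return prob >= threshold


def save_checkpoint(model: UNet3D, config: ModelConfig, path,
                    extra: dict | None = None) -> None:
    """Model weights (npz) plus a JSON sidecar with the full config."""
    path = Path(path)
    model.save(path)
    sidecar = {"model_config": asdict(config), "basis_name": "real_symmetric"}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[UNet3D, ModelConfig]:
    path = Path(path)
    model = UNet3D.load(path if path.suffix == ".npz"
                        else path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["model_config"]
    cfg_d["patch_shape"] = tuple(cfg_d["patch_shape"])
    return model, ModelConfig(**cfg_d)
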