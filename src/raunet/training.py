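"""Dice loss, patch/slice sampling, the training loop, and ensembling.

Training minimizes a soft Dice loss with Adam (lr 1e-3, β1 0.9, β2 0.999)
and multiplies the learning rate by 0.1 whenever the validation loss
plateaus for 20 epochs.  Patch sampling follows the two cascade stages:
liver patches are cut from the in-plane-resized boundary box, tumor patches
are taken at native resolution with centers balanced between tumor and
non-tumor liver voxels.  Everything stochastic is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DegenerateVolumeError,
    ShapeError,
    TrainingDivergedError,
)
from .ndnn import Adam, Module, ReduceLROnPlateau, Tensor, no_grad
from .preprocessing import Volume

DICE_EPS = 1e-5  # defines the empty/empty case as loss ~ 0


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings."""

    lr0: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    plateau_patience: int = 20
    lr_decay: float = 0.1
    min_delta: float = 1e-4
    epochs: int = 50
    folds: int = 5
    batch_size: int = 2
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lr_decay < 1.0:
            raise ConfigurationError("lr_decay must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ConfigurationError("plateau_patience must be >= 1")


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and per-volume sampling count for one cascade stage."""

    shape: tuple[int, int, int] = (224, 224, 32)
    count_per_volume: int = 30
    balanced: bool = False  # tumor stage: balance tumor / non-tumor centers


def liver_patch_spec(count_per_volume: int = 30, shape=(224, 224, 32)) -> PatchSpec:
    return PatchSpec(shape=tuple(shape), count_per_volume=count_per_volume, balanced=False)


def tumor_patch_spec(count_per_volume: int = 150, shape=(128, 128, 32)) -> PatchSpec:
    return PatchSpec(shape=tuple(shape), count_per_volume=count_per_volume, balanced=True)


@dataclass
class PatchPair:
    """One training sample: image, binary label, and a loss-validity mask."""

    image: np.ndarray  # (*spatial, 1) float32 in [0, 1]
    label: np.ndarray  # (*spatial, 1) float32 in {0, 1}
    loss_mask: np.ndarray | None = None  # zeros where padding was introduced


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def dice_loss(s, g, eps: float = DICE_EPS, mask=None):
    """Soft Dice loss  1 − (2Σs·g + ε) / (Σs² + Σg² + ε)  over all voxels.

    Accepts autodiff tensors (training path) or plain arrays.  ``mask``, if
    given, zeroes padded voxels out of every sum.
    """
    s_t = isinstance(s, Tensor)
    g_arr = g.data if isinstance(g, Tensor) else np.asarray(g)
    s_shape = s.shape if s_t else np.asarray(s).shape
    if tuple(s_shape) != tuple(g_arr.shape):
        raise ShapeError(f"dice_loss: shape mismatch {s_shape} vs {g_arr.shape}")
    if s_t:
        g_term = float((g_arr * g_arr * (mask if mask is not None else 1.0)).sum())
        if mask is not None:
            s = s * Tensor(mask)
        inter = (s * Tensor(g_arr * (mask if mask is not None else 1.0))).sum()
        s_sq = (s * s).sum()
        return 1.0 - (2.0 * inter + eps) / (s_sq + g_term + eps)
    s = np.asarray(s, dtype=np.float64)
    g_arr = g_arr.astype(np.float64)
    if mask is not None:
        s = s * mask
        g_arr = g_arr * mask
    inter = float((s * g_arr).sum())
    denom = float((s * s).sum() + (g_arr * g_arr).sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------

def _zoom_inplane(data: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    fx = target[0] / data.shape[0]
    fy = target[1] / data.shape[1]
    return ndimage.zoom(data, (fx, fy, 1.0), order=order, grid_mode=True, mode="grid-constant")


def sample_liver_patches(
    v: Volume,
    liver_mask: np.ndarray,
    box,
    spec: PatchSpec,
    seed: int,
) -> list[PatchPair]:
    """Random axial windows from the boundary box, in-plane resized.

    The box region is interpolated in-plane to the patch's in-plane size
    (keeping the axial length M), then ``count_per_volume`` windows of the
    full patch shape are cut at seeded random axial offsets.  Boxes thinner
    than the axial patch size are zero-padded and the padding is flagged in
    the loss mask.
    """
    rng = np.random.default_rng(seed)
    sx, sy, sz = spec.shape
    img = v.data[box.slices()].astype(np.float32)
    lbl = liver_mask[box.slices()].astype(np.float32)
    img = _zoom_inplane(img, (sx, sy), order=1)
    lbl = _zoom_inplane(lbl, (sx, sy), order=0)
    m = img.shape[2]
    valid_z = m
    if m < sz:
        pad = sz - m
        img = np.pad(img, ((0, 0), (0, 0), (0, pad)))
        lbl = np.pad(lbl, ((0, 0), (0, 0), (0, pad)))
        m = sz
    patches = []
    starts = rng.integers(0, m - sz + 1, size=spec.count_per_volume)
    for z0 in starts:
        sl = (slice(None), slice(None), slice(z0, z0 + sz))
        mask = None
        if valid_z < z0 + sz:
            mask = np.zeros((sx, sy, sz, 1), dtype=np.float32)
            mask[:, :, : max(valid_z - z0, 0)] = 1.0
        patches.append(PatchPair(
            image=img[sl][..., None].copy(),
            label=lbl[sl][..., None].copy(),
            loss_mask=mask,
        ))
    return patches


def sample_tumor_patches(
    v: Volume,
    liver_mask: np.ndarray,
    tumor_mask: np.ndarray,
    spec: PatchSpec,
    seed: int,
) -> list[PatchPair]:
    """Native-resolution windows whose centers lie inside the liver VOI.

    When the stage is balanced and tumor voxels exist, half the centers are
    drawn from tumor voxels and half from non-tumor liver voxels; a
    tumor-free liver degrades gracefully to liver-only centers.
    """
    if not liver_mask.any():
        raise DegenerateVolumeError("cannot sample tumor patches from an empty liver mask")
    rng = np.random.default_rng(seed)
    shape = np.asarray(v.data.shape)
    ps = np.asarray(spec.shape)
    if np.any(shape < ps):
        raise ConfigurationError(
            f"volume shape {tuple(shape)} smaller than patch shape {tuple(ps)}"
        )
    tumor_centers = np.argwhere(tumor_mask & liver_mask)
    liver_centers = np.argwhere(liver_mask & ~tumor_mask)
    if liver_centers.size == 0:
        liver_centers = np.argwhere(liver_mask)
    n = spec.count_per_volume
    n_tum = n // 2 if (spec.balanced and len(tumor_centers)) else 0
    picks = []
    if n_tum:
        picks.append(tumor_centers[rng.integers(0, len(tumor_centers), size=n_tum)])
    picks.append(liver_centers[rng.integers(0, len(liver_centers), size=n - n_tum)])
    centers = np.concatenate(picks, axis=0)
    patches = []
    for c in centers:
        start = np.clip(c - ps // 2, 0, shape - ps)
        sl = tuple(slice(int(s), int(s + p)) for s, p in zip(start, ps))
        patches.append(PatchPair(
            image=v.data[sl].astype(np.float32)[..., None],
            label=tumor_mask[sl].astype(np.float32)[..., None],
        ))
    return patches


def sample_liver_slices(
    v: Volume,
    liver_mask: np.ndarray,
    seed: int,
    size: int = 256,
    negative_ratio: float = 1.0 / 3.0,
) -> list[PatchPair]:
    """Axial slices for the 2D localization stage.

    Uses every slice containing liver plus `negative_ratio` as many randomly
    picked liver-free slices, all resized in-plane to ``size``×``size``.
    """
    rng = np.random.default_rng(seed)
    has_liver = liver_mask.any(axis=(0, 1))
    pos = np.flatnonzero(has_liver)
    neg = np.flatnonzero(~has_liver)
    n_neg = min(len(neg), int(round(negative_ratio * len(pos))))
    if n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    else:
        neg = np.empty(0, dtype=int)
    samples = []
    for z in np.concatenate([pos, np.sort(neg)]):
        img = v.data[:, :, int(z)].astype(np.float32)
        lbl = liver_mask[:, :, int(z)].astype(np.float32)
        fx, fy = size / img.shape[0], size / img.shape[1]
        img = ndimage.zoom(img, (fx, fy), order=1, grid_mode=True, mode="grid-constant")
        lbl = ndimage.zoom(lbl, (fx, fy), order=0, grid_mode=True, mode="grid-constant")
        samples.append(PatchPair(image=img[..., None], label=lbl[..., None]))
    return samples


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batch(pairs: list[PatchPair]):
    x = np.stack([p.image for p in pairs])
    y = np.stack([p.label for p in pairs])
    if any(p.loss_mask is not None for p in pairs):
        m = np.stack([
            p.loss_mask if p.loss_mask is not None else np.ones_like(p.label)
            for p in pairs
        ])
    else:
        m = None
    return x, y, m


def _eval_loss(network: Module, pairs: list[PatchPair], batch_size: int) -> float:
    network.eval()
    losses = []
    with no_grad():
        for i in range(0, len(pairs), batch_size):
            x, y, m = _batch(pairs[i:i + batch_size])
            pred = network(Tensor(x))
            losses.append(float(dice_loss(pred.data, y, mask=m)))
    return float(np.mean(losses))


def train(
    network: Module,
    patches: list[PatchPair],
    cfg: TrainConfig,
    progress=None,
) -> tuple[Module, pd.DataFrame]:
    """Seeded Adam/Dice training with plateau LR decay.

    Splits `patches` into train/validation (``val_fraction``; with fewer
    than five patches the train loss doubles as the validation loss),
    records per-epoch (train_loss, val_loss, lr), and raises
    :class:`TrainingDivergedError` on a non-finite loss.
    """
    if not patches:
        raise ConfigurationError("empty patch set")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(patches))
    n_val = int(round(cfg.val_fraction * len(patches))) if len(patches) >= 5 else 0
    val = [patches[i] for i in idx[:n_val]]
    tr = [patches[i] for i in idx[n_val:]]
    opt = Adam(network.parameters(), lr=cfg.lr0, beta1=cfg.beta1, beta2=cfg.beta2)
    sched = ReduceLROnPlateau(opt, factor=cfg.lr_decay,
                              patience=cfg.plateau_patience, min_delta=cfg.min_delta)
    history = []
    for epoch in range(cfg.epochs):
        network.train()
        order = rng.permutation(len(tr))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            x, y, m = _batch([tr[j] for j in order[i:i + cfg.batch_size]])
            opt.zero_grad()
            pred = network(Tensor(x))
            loss = dice_loss(pred, y, mask=m)
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}, step {i}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(network, val, cfg.batch_size) if val else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if progress is not None:
            progress(history[-1])
        sched.step(val_loss)
    return network, pd.DataFrame(history)


def evaluate_patch_dice(network: Module, patches: list[PatchPair],
                        threshold: float = 0.5) -> float:
    """Mean hard Dice of thresholded predictions over a patch set."""
    from .metrics import dice

    network.eval()
    scores = []
    with no_grad():
        for p in patches:
            pred = network(Tensor(p.image[None]))
            pm = pred.data[0] >= threshold
            gm = p.label.astype(bool)
            if p.loss_mask is not None:
                valid = p.loss_mask.astype(bool)
                pm, gm = pm & valid, gm & valid
            scores.append(dice(pm, gm))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# ensembling and cross-validation folds
# ---------------------------------------------------------------------------

def ensemble_predict(models: list[Module], patch: np.ndarray) -> np.ndarray:
    """Voxelwise mean probability over ensemble members (identical specs)."""
    if not models:
        raise ConfigurationError("ensemble requires at least one model")
    def arch(m):
        spec = getattr(m, "spec", None)
        if spec is None or not hasattr(spec, "to_dict"):
            return spec
        d = spec.to_dict()
        d.pop("seed", None)  # members differ only by initialization
        return tuple(sorted((k, str(v)) for k, v in d.items()))

    keys = [arch(m) for m in models]
    if any(k != keys[0] for k in keys[1:]):
        raise ConfigurationError("ensemble members must share one architecture")
    x = np.asarray(patch, dtype=np.float32)
    nd = models[0].spec.dimensionality
    if x.ndim == nd:  # bare spatial grid
        x = x[None, ..., None]
        restore = lambda a: a[0, ..., 0]
    elif x.ndim == nd + 1 and x.shape[-1] == 1:  # (*spatial, 1)
        x = x[None]
        restore = lambda a: a[0]
    elif x.ndim == nd + 2 and x.shape[-1] == 1:  # batched
        restore = lambda a: a
    else:
        raise ShapeError(f"cannot interpret patch shape {patch.shape} for a {nd}D model")
    acc = None
    with no_grad():
        for m in models:
            m.eval()
            out = m(Tensor(x)).data
            acc = out if acc is None else acc + out
    return restore(acc / len(models))


def kfold_split(has_tumor: list[bool], folds: int, seed: int) -> list[tuple[list[int], list[int]]]:
    """Volume-level k-fold split, stratified by tumor presence."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(has_tumor), dtype=int)
    for stratum in (True, False):
        members = [i for i, h in enumerate(has_tumor) if h == stratum]
        members = rng.permutation(members)
        for pos, i in enumerate(members):
            fold_of[i] = pos % folds
    splits = []
    for f in range(folds):
        val = [i for i in range(len(has_tumor)) if fold_of[i] == f]
        trn = [i for i in range(len(has_tumor)) if fold_of[i] != f]
        splits.append((trn, val))
    return splits
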