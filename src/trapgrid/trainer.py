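"""Patch-based training of the grid detector.

Each epoch draws ``patches_per_image`` random square patches from every
full-sized training image, builds a per-cell target grid from the box
centroids (a cell is a fly cell iff a fly-box centroid falls in its
footprint; bycatch counts as background), augments with the 8-element
dihedral group, and minimises a class-weighted per-cell cross entropy with
Adam under a two-phase learning-rate schedule. Flies cover a vanishing
fraction of a trap image, so the background class dominates the grid;
"auto" class weights use clamped inverse cell frequencies to keep the fly
classes in play.

Validation runs at full-image scale with the point-matching metric every
``validate_every`` epochs and the checkpoint with the best validation AUC
(fly classes combined) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _nn as nn
from .annotations_io import AnnotatedImage, BBox, box_centroid
from .grid_detector import IDX_DSF, IDX_DSM, GridModel, detect_image
from .evaluator import MatchConfig, pooled_pr_curve

#: grid label codes, aligned with the detector's class channels
LABEL_CODE = {"DSF": IDX_DSF, "DSM": IDX_DSM}

Sample = tuple[np.ndarray, AnnotatedImage]  # (HWC uint8 image, annotation)


@dataclass(frozen=True)
class TrainConfig:
    patches_per_image: int = 16
    patch_size: int = 512
    batch_size: int = 4
    lr_phase1: float = 1e-5
    epochs_phase1: int = 50
    lr_phase2: float = 1e-6
    epochs_phase2: int = 250
    class_weights: tuple[float, float, float] | str = "auto"
    seed: int = 0
    validate_every: int = 10

    def __post_init__(self):
        if min(self.patches_per_image, self.patch_size, self.batch_size) <= 0:
            raise ValueError("counts must be positive")
        if self.lr_phase1 <= 0 or self.lr_phase2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.lr_phase2 > self.lr_phase1:
            raise ValueError("phase-2 learning rate must not exceed phase 1")
        if self.epochs_phase1 < 0 or self.epochs_phase2 < 0:
            raise ValueError("epoch counts must be >= 0")


@dataclass
class TargetGrid:
    """Per-cell class labels {0 background, 1 DSF, 2 DSM} for one patch."""

    labels: np.ndarray


# --------------------------------------------------------------------------
# Patch sampling and target construction
# --------------------------------------------------------------------------

def make_target_grid(boxes: Sequence[BBox], patch_origin: tuple[int, int],
                     patch_size: int, stride: int) -> TargetGrid:
    """Label each stride x stride cell by the fly-box centroids it contains.

    A clipped box still counts iff its centroid lies inside the patch.
    Bycatch centroids map to background. When centroids of different
    classes share a cell, the centroid nearest the cell centre wins.
    """
    g = patch_size // stride
    labels = np.zeros((g, g), dtype=np.int64)
    best = np.full((g, g), np.inf)
    ox, oy = patch_origin
    for b in boxes:
        code = LABEL_CODE.get(b.label)
        if code is None:  # BC -> background
            continue
        cx, cy = box_centroid(b)
        px, py = cx - ox, cy - oy
        if not (0 <= px < patch_size and 0 <= py < patch_size):
            continue
        row, col = int(py // stride), int(px // stride)
        ccx, ccy = (col + 0.5) * stride, (row + 0.5) * stride
        d = (px - ccx) ** 2 + (py - ccy) ** 2
        if d < best[row, col]:
            best[row, col] = d
            labels[row, col] = code
    return TargetGrid(labels=labels)


def sample_patches(ann: AnnotatedImage, image: np.ndarray, k: int,
                   patch_size: int, stride: int, *, seed: int
                   ) -> list[tuple[np.ndarray, TargetGrid]]:
    """Crop ``k`` random patches with their target grids, reproducibly.

    Images at least ``patch_size`` on both sides get uniformly random
    top-left corners. A smaller image (tiny-variant training scenes) is
    used whole as a single repeated patch, provided its sides divide the
    stride evenly.
    """
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        if h % stride or w % stride:
            raise ValueError(
                f"image {w}x{h} smaller than patch {patch_size} and not "
                f"divisible by stride {stride}")
        tg = TargetGrid(labels=_full_image_targets(ann, h, w, stride))
        return [(image, tg) for _ in range(k)]
    out = []
    for _ in range(k):
        x0 = int(rng.integers(0, w - patch_size + 1))
        y0 = int(rng.integers(0, h - patch_size + 1))
        patch = image[y0:y0 + patch_size, x0:x0 + patch_size]
        tg = make_target_grid(ann.boxes, (x0, y0), patch_size, stride)
        out.append((patch, tg))
    return out


def _full_image_targets(ann: AnnotatedImage, h: int, w: int,
                        stride: int) -> np.ndarray:
    rows, cols = h // stride, w // stride
    labels = np.zeros((rows, cols), dtype=np.int64)
    best = np.full((rows, cols), np.inf)
    for b in ann.boxes:
        code = LABEL_CODE.get(b.label)
        if code is None:
            continue
        cx, cy = box_centroid(b)
        row, col = int(cy // stride), int(cx // stride)
        if row >= rows or col >= cols:
            continue
        d = (cx - (col + 0.5) * stride) ** 2 + (cy - (row + 0.5) * stride) ** 2
        if d < best[row, col]:
            best[row, col] = d
            labels[row, col] = code
    return labels


# --------------------------------------------------------------------------
# Augmentation: the dihedral group of the square
# --------------------------------------------------------------------------

def apply_dihedral(arr: np.ndarray, transform: int) -> np.ndarray:
    """Apply one of the 8 square symmetries (index 0 is the identity).

    ``transform = flip * 4 + rot`` with ``rot`` counter-clockwise quarter
    turns applied first, then an optional horizontal flip.
    """
    if not 0 <= transform < 8:
        raise ValueError("transform index must be in [0, 8)")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("dihedral transforms require a square array")
    rot, flip = transform % 4, transform // 4
    out = np.rot90(arr, rot, axes=(0, 1))
    if flip:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def invert_dihedral(transform: int) -> int:
    """Index of the inverse square symmetry."""
    rot, flip = transform % 4, transform // 4
    inv_rot = rot if flip else (-rot) % 4
    return flip * 4 + inv_rot


def augment(patch: np.ndarray, target: TargetGrid, *, seed: int | None = None,
            rng: np.random.Generator | None = None
            ) -> tuple[np.ndarray, TargetGrid]:
    """Random flip/rotation augmentation, identical on patch and targets."""
    if rng is None:
        rng = np.random.default_rng(seed)
    t = int(rng.integers(8))
    return (apply_dihedral(patch, t),
            TargetGrid(labels=apply_dihedral(target.labels, t)))


# --------------------------------------------------------------------------
# Class weights and the optimisation loop
# --------------------------------------------------------------------------

def auto_class_weights(train_set: Sequence[Sample], stride: int
                       ) -> np.ndarray:
    """Inverse cell-class frequencies over the training set, clamped [1, 100]."""
    counts = np.zeros(3, dtype=np.float64)
    for image, ann in train_set:
        h, w = image.shape[:2]
        labels = _full_image_targets(ann, h, w, stride)
        counts += np.bincount(labels.reshape(-1), minlength=3)
    total = counts.sum()
    weights = np.where(counts > 0, total / (3.0 * np.maximum(counts, 1)), 100.0)
    return np.clip(weights, 1.0, 100.0).astype(np.float32)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    val_auc: float | None = None


def _val_loss(model: GridModel, val_set: Sequence[Sample], patch_size: int,
              weights: np.ndarray) -> float:
    """Deterministic validation loss on one top-left patch per image."""
    losses = []
    for image, ann in val_set:
        h, w = image.shape[:2]
        stride = model.cfg.stride
        if h < patch_size or w < patch_size:
            patch = image
            tg = TargetGrid(labels=_full_image_targets(ann, h, w, stride))
        else:
            patch = image[:patch_size, :patch_size]
            tg = make_target_grid(ann.boxes, (0, 0), patch_size, stride)
        logits = model.forward_logits(model._prep(patch), train=False)
        loss, _ = nn.weighted_cross_entropy(logits, tg.labels[None], weights)
        losses.append(loss)
    return float(np.mean(losses))


def _val_auc(model: GridModel, val_set: Sequence[Sample],
             match_cfg: MatchConfig) -> float:
    groups = []
    for image, ann in val_set:
        dets, _ = detect_image(model, image)
        groups.append((dets, ann.fly_boxes()))
    if not any(g for _, g in groups):
        return 0.0
    cfg = MatchConfig(dist_threshold=match_cfg.dist_threshold, class_mode="both")
    return pooled_pr_curve(groups, cfg).auc


def train(model: GridModel, train_set: Sequence[Sample],
          val_set: Sequence[Sample], cfg: TrainConfig,
          match_cfg: MatchConfig | None = None
          ) -> tuple[GridModel, list[EpochRecord]]:
    """Two-phase Adam training; returns the best-on-validation model.

    Model selection is by validation AUC (fly classes combined) computed
    every ``cfg.validate_every`` epochs; epochs in between fall back to the
    validation loss. Training aborts with a diagnostic if the loss becomes
    non-finite.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    match_cfg = match_cfg or MatchConfig()
    rng = np.random.default_rng(cfg.seed)
    model.dropout.rng = np.random.default_rng(cfg.seed + 1)

    if cfg.class_weights == "auto":
        weights = auto_class_weights(train_set, model.cfg.stride)
    else:
        weights = np.asarray(cfg.class_weights, dtype=np.float32)
        if weights.shape != (3,):
            raise ValueError("class_weights must be a 3-vector or 'auto'")

    optim = nn.Adam(model.parameters(), lr=cfg.lr_phase1)
    total_epochs = cfg.epochs_phase1 + cfg.epochs_phase2
    history: list[EpochRecord] = []
    best = {"score": -np.inf, "params": None, "bn": None, "has_auc": False}

    def snapshot():
        best["params"] = [p.data.copy() for p in model.parameters()]
        best["bn"] = [(bn.running_mean.copy(), bn.running_var.copy())
                      for bn in model._batchnorms()]

    for epoch in range(1, total_epochs + 1):
        optim.lr = cfg.lr_phase1 if epoch <= cfg.epochs_phase1 else cfg.lr_phase2
        pairs: list[tuple[np.ndarray, TargetGrid]] = []
        for image, ann in train_set:
            pk = sample_patches(ann, image, cfg.patches_per_image,
                                cfg.patch_size, model.cfg.stride,
                                seed=int(rng.integers(2 ** 31)))
            pairs.extend(augment(p, t, rng=rng) for p, t in pk)
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for i0 in range(0, len(order), cfg.batch_size):
            batch = [pairs[j] for j in order[i0:i0 + cfg.batch_size]]
            x = model._prep(np.stack([p for p, _ in batch]))
            y = np.stack([t.labels for _, t in batch])
            logits = model.forward_logits(x, train=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            optim.zero_grad()
            model.backward(dlogits)
            optim.step()
            epoch_losses.append(loss)

        vloss = _val_loss(model, val_set, cfg.patch_size, weights)
        vauc = None
        if cfg.validate_every and (epoch % cfg.validate_every == 0
                                   or epoch == total_epochs):
            vauc = _val_auc(model, val_set, match_cfg)
        history.append(EpochRecord(epoch=epoch, lr=optim.lr,
                                   train_loss=float(np.mean(epoch_losses)),
                                   val_loss=vloss, val_auc=vauc))
        # selection: validation AUC when available, else validation loss
        if vauc is not None:
            if vauc >= best["score"] or not best["has_auc"]:
                best["score"], best["has_auc"] = vauc, True
                snapshot()
        elif not best["has_auc"] and -vloss >= best["score"]:
            best["score"] = -vloss
            snapshot()

    if best["params"] is not None:
        for p, data in zip(model.parameters(), best["params"]):
            p.data[...] = data
        for bn, (m, v) in zip(model._batchnorms(), best["bn"]):
            bn.running_mean, bn.running_var = m.copy(), v.copy()
    return model, history
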