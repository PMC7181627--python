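"""Dataset configurations, cross-validation, and curriculum training.

Annotation modes mirror how clinicians annotate hydrops MRI:

* ``SA``    — selectively annotated: only the side's organ of interest (the
  most obviously visible organ) carries a label;
* ``FA``    — fully annotated: every visible organ carries a label;
* ``FASA``  — the union of the two patch pools;
* ``FA'``   — the FA patches restricted to the organ-of-interest class;
* ``FA'SA`` — FA' plus SA.

Each original patch is one (subject, side, slice) window of the MRC stack,
fed to the network as a min-max-normalized slice triplet. 5-fold
cross-validation partitions the *original* patch ids (augmented variants
follow their original, so folds never leak augmented copies of a validation
patch into training). The curriculum schedule trains on the simple SA pool
first, then resumes the weights and fine-tunes on a harder pool, validating
on held-out patches throughout.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentationPolicy, Scale, augment_patch
from .imageops import CropSpec, crop_patch, minmax01
from .segnet import SegModelConfig, SegNet, argmax_labels, build_model, make_triplet
from .stack import BACKGROUND, LABEL_NAMES, NAME_TO_LABEL, ORGAN_LABELS, SubjectStack

logger = logging.getLogger(__name__)

AnnotationMode = Literal["SA", "FA", "FASA", "FA'", "FA'SA"]


@dataclass(frozen=True)
class DatasetConfig:
    """Which annotation pool feeds training, and at which augmentation scale."""

    annotation_mode: AnnotationMode = "SA"
    augmentation: Literal["none", "low", "moderate", "high"] = "none"
    k_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam throughout)."""

    learning_rate: float = 1e-6
    dropout: float = 0.6
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    fine_tune_from: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class Sample:
    """One network sample: a normalized slice triplet plus its label patch."""

    x: np.ndarray  # (3, h, w) float
    y: np.ndarray  # (h, w) uint8 labels
    sample_id: str
    origin_id: str  # original-patch id (augmented variants share it)
    subject_id: str
    side: str
    pool: str  # "SA" or "FA"
    classes_of_interest: Tuple[int, ...]  # labels scored during validation


# ---------------------------------------------------------------------------
# dataset assembly


def _mask_for_mode(
    mask_patch: np.ndarray, mode: AnnotationMode, pool: str, ooi: int, visible: Dict[int, bool]
) -> np.ndarray:
    keep: set
    if mode == "SA" or (mode == "FASA" and pool == "SA") or (
        mode == "FA'SA" and pool == "SA"
    ):
        keep = {ooi}
    elif mode == "FA'" or (mode == "FA'SA" and pool == "FA"):
        keep = {ooi}
    else:  # FA, or the FA half of FASA: all visible organs
        keep = {lab for lab, v in visible.items() if v}
    out = mask_patch.copy()
    out[~np.isin(out, list(keep))] = BACKGROUND
    return out


def _pools_for_mode(mode: AnnotationMode) -> set:
    return {"SA": {"SA"}, "FA": {"FA"}, "FA'": {"FA"}, "FASA": {"SA", "FA"},
            "FA'SA": {"SA", "FA"}}[mode]


def build_patch_dataset(
    subjects: Sequence[SubjectStack],
    manifest: pd.DataFrame,
    crop: CropSpec,
    mode: AnnotationMode = "SA",
    augmentation: Literal["none", "low", "moderate", "high"] = "none",
    policy: Optional[AugmentationPolicy] = None,
) -> List[Sample]:
    """Assemble the training samples for one annotation mode.

    With ``augmentation != "none"`` every original patch is expanded into
    its full variant set (the same geometric transform applied to all three
    triplet slices; brightness applied before normalization).
    """
    pools = _pools_for_mode(mode)
    by_subject = {
        sid: df for sid, df in manifest.groupby("subject_id")
    }
    samples: List[Sample] = []
    for stack in subjects:
        rows = by_subject[stack.subject_id]
        for side in ("left", "right"):
            side_rows = rows[rows["side"] == side]
            pool = side_rows["annotation_pool"].iloc[0]
            if pool not in pools:
                continue
            ooi = int(side_rows.loc[side_rows["organ_of_interest"], "label"].iloc[0])
            visible = dict(zip(side_rows["label"].astype(int), side_rows["visible"]))
            # validation IoU is scored on the side's organ of interest only
            interest: Tuple[int, ...] = (ooi,)
            mrc_patches = [
                crop_patch(stack.mrc[k], side, crop).data for k in range(stack.n_slices)
            ]
            for k in range(stack.n_slices):
                origin_id = f"{stack.subject_id}:{side}:{k}"
                mask_patch = crop_patch(stack.masks[k], side, crop).data
                y = _mask_for_mode(mask_patch, mode, pool, ooi, visible)
                if augmentation == "none":
                    trip = make_triplet(mrc_patches, k).as_array()
                    x = np.stack([minmax01(p) for p in trip], axis=0)
                    samples.append(
                        Sample(x, y, origin_id, origin_id, stack.subject_id, side,
                               pool, interest)
                    )
                    continue
                pol = policy if policy is not None else AugmentationPolicy()
                kp = k - 1 if k > 0 else k
                kn = k + 1 if k < stack.n_slices - 1 else k
                per_slice = [
                    augment_patch(stack.mrc[j], stack.masks[j], side, crop, pol,
                                  scale=augmentation)
                    for j in (kp, k, kn)
                ]
                for v in range(len(per_slice[1])):
                    x = np.stack(
                        [minmax01(per_slice[j][v][0]) for j in range(3)], axis=0
                    )
                    yv = _mask_for_mode(per_slice[1][v][1], mode, pool, ooi, visible)
                    samples.append(
                        Sample(x, yv, f"{origin_id}#aug{v}", origin_id,
                               stack.subject_id, side, pool, interest)
                    )
    return samples


# ---------------------------------------------------------------------------
# folds and metric


def make_folds(patch_ids: Sequence[str], k: int = 5, seed: int = 0) -> Dict[str, int]:
    """Random equal-sized partition of patch ids into k folds (sizes differ <= 1)."""
    ids = list(patch_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patch ids must be unique")
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} patches")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[int(j)]: int(i % k) for i, j in enumerate(order)}


def iou_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Area of overlap / area of union for two binary masks (1 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mean_iou(
    pred: np.ndarray, gt: np.ndarray, classes: Optional[Sequence[int]] = None
) -> float:
    """Unweighted mean per-class IoU over organ classes present in ``gt``.

    Background is excluded. ``classes`` restricts the average (e.g. to the
    organs of interest); classes absent from both masks are skipped, and a
    class absent from ``gt`` but predicted is skipped with a log entry.
    Returns NaN if no class qualifies.
    """
    cand = tuple(classes) if classes is not None else ORGAN_LABELS
    scores = []
    for c in cand:
        if c == BACKGROUND:
            continue
        in_gt = bool((gt == c).any())
        in_pred = bool((pred == c).any())
        if not in_gt:
            if in_pred:
                logger.debug("class %s predicted but absent from ground truth; skipped",
                             LABEL_NAMES.get(c, c))
            continue
        scores.append(iou_binary(pred == c, gt == c))
    return float(np.mean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    epoch_val_iou: List[float]
    best_epoch: int
    best_iou: float
    best_state: Dict[str, np.ndarray]
    final_state: Dict[str, np.ndarray]
    losses: List[float]


def evaluate(model: SegNet, samples: Sequence[Sample], batch_size: int = 8) -> float:
    """Mean over samples of per-sample IoU on each sample's classes of interest."""
    scores = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        x = np.stack([s.x for s in chunk], axis=0)
        labels = argmax_labels(model.forward(x, train=False))
        for j, s in enumerate(chunk):
            v = mean_iou(labels[j], s.y, classes=s.classes_of_interest)
            if not np.isnan(v):
                scores.append(v)
    return float(np.mean(scores)) if scores else float("nan")


def fit(
    model: SegNet,
    train_samples: Sequence[Sample],
    val_samples: Sequence[Sample],
    cfg: TrainConfig,
) -> FitResult:
    """Adam training loop with per-epoch validation IoU tracking.

    Deterministic given (model seed, cfg.seed, sample order). The best
    epoch is selected by validation IoU; both the best and the final
    weights are returned (curriculum fine-tuning resumes from the final
    weights).
    """
    if cfg.fine_tune_from is not None:
        model.load_state_dict(cfg.fine_tune_from)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    epoch_iou: List[float] = []
    losses: List[float] = []
    best_iou, best_epoch = -np.inf, -1
    best_state = model.state_dict()
    n = len(train_samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i in range(0, n, cfg.batch_size):
            batch = [train_samples[int(j)] for j in order[i : i + cfg.batch_size]]
            x = np.stack([s.x for s in batch], axis=0)
            y = np.stack([s.y for s in batch], axis=0).astype(np.int64)
            scores = model.forward(x, train=True, rng=rng)
            loss, dscores = nn.softmax_cross_entropy(scores, y)
            model.backward(dscores)
            opt.step()
            opt.zero_grad()
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / max(nb, 1))
        v = evaluate(model, val_samples) if val_samples else float("nan")
        epoch_iou.append(v)
        if v > best_iou:
            best_iou, best_epoch = v, epoch
            best_state = model.state_dict()
    if cfg.epochs == 0:
        best_iou, best_epoch = float("nan"), -1
    return FitResult(
        epoch_val_iou=epoch_iou,
        best_epoch=best_epoch,
        best_iou=float(best_iou) if np.isfinite(best_iou) else float("nan"),
        best_state=best_state,
        final_state=model.state_dict(),
        losses=losses,
    )


@dataclass
class CVResult:
    fold_ious: List[float]
    curves: List[List[float]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_ious))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_ious, ddof=1)) if len(self.fold_ious) > 1 else 0.0


def run_cv(
    samples: Sequence[Sample],
    model_cfg: SegModelConfig,
    train_cfg: TrainConfig,
    k: int = 5,
) -> CVResult:
    """k-fold cross-validation over original patches.

    Each round trains on (k-1)/k of the originals and validates on the
    held-out fold; the per-fold score is the best-epoch validation IoU, and
    the aggregate is their mean +- SD.
    """
    origin_ids = sorted({s.origin_id for s in samples})
    folds = make_folds(origin_ids, k=k, seed=train_cfg.seed)
    model_cfg = dataclasses.replace(model_cfg, dropout=train_cfg.dropout)
    fold_ious: List[float] = []
    curves: List[List[float]] = []
    for f in range(k):
        train_s = [s for s in samples if folds[s.origin_id] != f]
        # validate on originals only: augmented variants of held-out patches
        # are not scored
        val_s = [s for s in samples if folds[s.origin_id] == f and "#aug" not in s.sample_id]
        model = build_model(model_cfg, seed=train_cfg.seed * 1000 + f)
        res = fit(model, train_s, val_s,
                  dataclasses.replace(train_cfg, seed=train_cfg.seed * 1000 + f))
        fold_ious.append(res.best_iou)
        curves.append(res.epoch_val_iou)
    return CVResult(fold_ious=fold_ious, curves=curves)


def curriculum_train(
    stage1_samples: Sequence[Sample],
    stage2_samples: Sequence[Sample],
    val_samples: Sequence[Sample],
    model_cfg: SegModelConfig,
    stage1_cfg: TrainConfig,
    stage2_cfg: TrainConfig,
) -> Tuple[SegNet, FitResult, FitResult]:
    """Two-stage curriculum: train from scratch on the simple pool, then
    resume the weights and fine-tune on the harder pool.

    Validation (the same held-out samples, typically from the combined
    pool) is tracked throughout; with 0 fine-tune epochs the returned model
    is identical to the stage-1 output.
    """
    model_cfg = dataclasses.replace(model_cfg, dropout=stage1_cfg.dropout)
    model = build_model(model_cfg, seed=stage1_cfg.seed)
    res1 = fit(model, stage1_samples, val_samples, stage1_cfg)
    model.load_state_dict(res1.final_state)
    res2 = fit(model, stage2_samples, val_samples,
               dataclasses.replace(stage2_cfg, fine_tune_from=None))
    if stage2_cfg.epochs == 0:
        model.load_state_dict(res1.final_state)
    else:
        model.load_state_dict(res2.final_state)
    return model, res1, res2
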