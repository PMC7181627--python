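"""Pre-registered phantom experiments at desk scale.

These functions bundle the package's reference study conditions so the same
experiment can be run from the test suite, the acceptance script and the
examples. Conditions are frozen here rather than passed ad hoc:

* EH-ratio fidelity: 50 noiseless full-geometry phantoms (384x324 frames,
  100-px windows), true endolymph fractions uniform on (0.1, 0.6); the
  ground-truth-mask EH ratio must recover the specified fraction to within
  one pixel, and agree with the truth at ICC >= 0.99.
* Directional training comparisons: 8 subjects at 0.24 geometry scale
  (24-px windows), MRC noise SD 60 on the 0-1000 scale, encoder depth 8,
  channel scale 0.125, Adam lr 3e-3, dropout 0.1, batch 4 — a regime where
  a from-scratch run reaches mid-range IoU within 20 epochs on one CPU.
  The comparisons assert orderings only (which architecture / schedule is
  better), not absolute IoU values, which are not transferable from
  phantoms to clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .phantom import CohortRanges, PhantomSpec, generate_cohort
from .quantify import cohort_eh_report, icc_single_two_way
from .segnet import SegModelConfig
from .train import (
    CVResult,
    TrainConfig,
    build_patch_dataset,
    curriculum_train,
    fit,
    make_folds,
    run_cv,
)
from .segnet import build_model

#: desk-scale training regime (see module docstring)
DESK_GEOMETRY_SCALE = 0.24
DESK_N_SUBJECTS = 8
DESK_NOISE_SD = 60.0
DESK_MODEL = dict(encoder_depth=8, channel_scale=0.125)
DESK_TRAIN = dict(learning_rate=3e-3, dropout=0.1, batch_size=4)
DESK_CV_EPOCHS = 20
DESK_CURRICULUM_EPOCHS = (10, 10)  # stage 1 + stage 2 = matched 20-epoch budget


def eh_fidelity_experiment(
    n_subjects: int = 50, seed: int = 0
) -> Dict[str, float]:
    """Ground-truth-mask EH ratios vs true fractions on a noiseless cohort.

    Returns the maximum per-organ absolute error in units of one pixel of
    the organ's area (<= 1 means within quantization), the raw maximum
    absolute error, and the ICC between measured ratio and true fraction.
    """
    spec = PhantomSpec(noise_sd=0.0)
    ranges = CohortRanges(endolymph_fraction=(0.1, 0.6), noise_sd=(0.0, 0.0))
    subjects, manifest = generate_cohort(n_subjects, spec, ranges, seed=seed)
    report = cohort_eh_report(subjects)
    merged = report.merge(
        manifest[["subject_id", "label", "requested_fraction"]],
        on=["subject_id", "label"],
    )
    err = (merged["gt_ratio"] - merged["requested_fraction"]).abs()
    err_pixels = err * merged["gt_total_pixels"]
    icc, _ = icc_single_two_way(merged["gt_ratio"], merged["requested_fraction"])
    return {
        "max_error_pixels": float(err_pixels.max()),
        "max_abs_error": float(err.max()),
        "icc": float(icc),
        "n_pairs": int(len(merged)),
    }


def _desk_cohort(seed: int):
    spec = PhantomSpec(noise_sd=DESK_NOISE_SD).scaled(DESK_GEOMETRY_SCALE)
    ranges = CohortRanges(
        endolymph_fraction=(0.1, 0.6), noise_sd=(DESK_NOISE_SD, DESK_NOISE_SD)
    )
    subjects, manifest = generate_cohort(DESK_N_SUBJECTS, spec, ranges, seed=seed)
    return spec, subjects, manifest


def variant_comparison_experiment(seed: int = 1) -> Dict[str, CVResult]:
    """5-fold CV IoU of the two architectures on the same phantom dataset."""
    spec, subjects, manifest = _desk_cohort(seed + 10)
    samples = build_patch_dataset(subjects, manifest, spec.crop, mode="FASA")
    tcfg = TrainConfig(epochs=DESK_CV_EPOCHS, seed=seed, **DESK_TRAIN)
    results = {}
    for variant in ("3into3", "concat3into1"):
        cfg = SegModelConfig(variant=variant, **DESK_MODEL)
        results[variant] = run_cv(samples, cfg, tcfg, k=5)
    return results


def curriculum_comparison_experiment(seed: int = 1) -> Dict[str, float]:
    """Curriculum (simple pool, then fine-tune on the union) vs training the
    union from scratch, at a matched total epoch budget and shared seeds."""
    spec, subjects, manifest = _desk_cohort(seed + 10)
    fasa = build_patch_dataset(subjects, manifest, spec.crop, mode="FASA")
    sa = build_patch_dataset(subjects, manifest, spec.crop, mode="SA")
    folds = make_folds(sorted({s.origin_id for s in fasa}), k=5, seed=seed)
    val = [s for s in fasa if folds[s.origin_id] == 0]
    fasa_tr = [s for s in fasa if folds[s.origin_id] != 0]
    sa_tr = [s for s in sa if folds[s.origin_id] != 0]

    e1, e2 = DESK_CURRICULUM_EPOCHS
    cfg = SegModelConfig(variant="3into3", **DESK_MODEL)
    _, _, res2 = curriculum_train(
        sa_tr, fasa_tr, val, cfg,
        TrainConfig(epochs=e1, seed=seed, **DESK_TRAIN),
        TrainConfig(epochs=e2, seed=seed + 1, **DESK_TRAIN),
    )
    scratch_model = build_model(cfg, seed=seed)
    res_scratch = fit(
        scratch_model, fasa_tr, val, TrainConfig(epochs=e1 + e2, seed=seed, **DESK_TRAIN)
    )
    return {
        "curriculum_best_iou": res2.best_iou,
        "scratch_best_iou": res_scratch.best_iou,
    }
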