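"""End-to-end pipeline orchestration with content-addressed stage caching.

Stages run in dependency order::

    phantom -> derive ------------------\\
            \\-> train -> predict -> quantify

Every stage writes its artifacts under ``out_dir/<stage>/`` together with a
stamp recording the hash of the configuration slice it depends on. A re-run
with the same configuration skips completed stages (idempotence); a stage
re-executes when its stamp is stale, its outputs are missing, or an
upstream stage re-executed. Seeds are mandatory configuration — nothing is
derived from the wall clock.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dataio import load_subject, write_outputs, write_subject, _write_nifti, _read_nifti
from .imageops import compute_hydrops, compute_hydrops_mi2
from .phantom import CohortRanges, PhantomSpec, generate_cohort
from .quantify import agreement_report, cohort_eh_report
from .segnet import SegModelConfig, build_model, predict_masks
from .train import (
    DatasetConfig,
    TrainConfig,
    build_patch_dataset,
    evaluate,
    fit,
    make_folds,
)


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable via from_dict)."""

    out_dir: Path
    seed: int = 0
    n_subjects: int = 10
    phantom_scale: float = 0.32  # geometry factor; 1.0 = full 384x324 frames
    fraction_range: tuple = (0.1, 0.6)
    noise_sd: float = 20.0
    dataset: DatasetConfig = field(default_factory=lambda: DatasetConfig("FASA"))
    model: SegModelConfig = field(
        default_factory=lambda: SegModelConfig(channel_scale=0.125, encoder_depth=8)
    )
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=1e-3, dropout=0.1, epochs=3)
    )
    stages: tuple = ("phantom", "derive", "train", "predict", "quantify")
    force: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "dataset" in d:
            d["dataset"] = DatasetConfig(**d["dataset"])
        if "model" in d:
            d["model"] = SegModelConfig(**d["model"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "fraction_range" in d:
            d["fraction_range"] = tuple(d["fraction_range"])
        d["out_dir"] = Path(d["out_dir"])
        return cls(**d)


def _cfg_hash(obj) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    return hashlib.sha256(
        json.dumps(obj, default=enc, sort_keys=True).encode()
    ).hexdigest()[:16]


class _Stage:
    def __init__(self, name: str, out_dir: Path, cfg_slice, upstream_ran: bool):
        self.name = name
        self.dir = Path(out_dir) / name
        self.stamp_path = self.dir / ".stamp.json"
        self.hash = _cfg_hash(cfg_slice)
        self.upstream_ran = upstream_ran

    def fresh(self) -> bool:
        if self.upstream_ran or not self.stamp_path.exists():
            return False
        try:
            return json.loads(self.stamp_path.read_text())["hash"] == self.hash
        except Exception:
            return False

    def start(self) -> None:
        if self.dir.exists():
            shutil.rmtree(self.dir)
        self.dir.mkdir(parents=True)

    def finish(self) -> None:
        self.stamp_path.write_text(
            json.dumps({"hash": self.hash, "version": __version__})
        )


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Execute the selected stages; returns per-stage status and key paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: Dict[str, str] = {}
    result: Dict[str, object] = {"status": status, "out_dir": out}

    base_spec = PhantomSpec(noise_sd=cfg.noise_sd).scaled(cfg.phantom_scale)
    ranges = CohortRanges(
        endolymph_fraction=cfg.fraction_range, noise_sd=(cfg.noise_sd, cfg.noise_sd)
    )
    crop = base_spec.crop

    # ---- phantom ----------------------------------------------------------
    ph_cfg = dict(seed=cfg.seed, n=cfg.n_subjects, spec=base_spec, ranges=ranges)
    ph = _Stage("phantom", out, ph_cfg, upstream_ran=cfg.force)
    subjects = manifest = None
    if "phantom" in cfg.stages and not ph.fresh():
        ph.start()
        subjects, manifest = generate_cohort(cfg.n_subjects, base_spec, ranges, cfg.seed)
        for s in subjects:
            write_subject(s, ph.dir / s.subject_id, fmt="png")
        manifest.to_csv(ph.dir / "manifest.csv", index=False)
        ph.finish()
        status["phantom"] = "run"
    else:
        status["phantom"] = "skipped"

    def _load_cohort():
        nonlocal subjects, manifest
        if subjects is None:
            if not (ph.dir / "manifest.csv").exists():
                raise DependencyError("phantom stage output missing; run 'phantom' first")
            manifest = pd.read_csv(ph.dir / "manifest.csv")
            subjects = [
                load_subject(d)
                for d in sorted(p for p in ph.dir.iterdir() if p.is_dir())
            ]
        return subjects, manifest

    # ---- derive -----------------------------------------------------------
    dv = _Stage("derive", out, {"up": ph.hash}, upstream_ran=status["phantom"] == "run")
    if "derive" in cfg.stages and not dv.fresh():
        subs, _ = _load_cohort()
        dv.start()
        for s in subs:
            hyd = compute_hydrops(s.ppi, s.pei)
            mi2 = compute_hydrops_mi2(hyd, s.mrc)
            _write_nifti(hyd, dv.dir / f"{s.subject_id}_hydrops.nii.gz")
            _write_nifti(mi2, dv.dir / f"{s.subject_id}_hydrops_mi2.nii.gz")
        dv.finish()
        status["derive"] = "run"
    else:
        status["derive"] = "skipped" if "derive" in cfg.stages else "not-selected"

    # ---- train ------------------------------------------------------------
    tr_cfg = {"up": ph.hash, "dataset": cfg.dataset, "model": cfg.model,
              "train": cfg.train}
    tr = _Stage("train", out, tr_cfg, upstream_ran=status["phantom"] == "run")
    if "train" in cfg.stages and not tr.fresh():
        subs, man = _load_cohort()
        tr.start()
        samples = build_patch_dataset(
            subs, man, crop, mode=cfg.dataset.annotation_mode,
            augmentation=cfg.dataset.augmentation,
        )
        folds = make_folds(sorted({s.origin_id for s in samples}),
                           k=cfg.dataset.k_folds, seed=cfg.dataset.seed)
        train_s = [s for s in samples if folds[s.origin_id] != 0]
        val_s = [s for s in samples if folds[s.origin_id] == 0]
        model_cfg = dataclasses.replace(cfg.model, dropout=cfg.train.dropout)
        model = build_model(model_cfg, seed=cfg.train.seed)
        res = fit(model, train_s, val_s, cfg.train)
        np.savez(tr.dir / "checkpoint.npz", **res.best_state)
        (tr.dir / "metrics.json").write_text(json.dumps({
            "best_epoch": res.best_epoch, "best_iou": res.best_iou,
            "epoch_val_iou": res.epoch_val_iou, "losses": res.losses,
        }))
        (tr.dir / "model_config.json").write_text(
            json.dumps(dataclasses.asdict(model_cfg))
        )
        tr.finish()
        status["train"] = "run"
    else:
        status["train"] = "skipped" if "train" in cfg.stages else "not-selected"

    # ---- predict ----------------------------------------------------------
    pr = _Stage("predict", out, {"up": tr.hash}, upstream_ran=status["train"] == "run")
    if "predict" in cfg.stages and not pr.fresh():
        subs, _ = _load_cohort()
        if not (tr.dir / "checkpoint.npz").exists():
            raise DependencyError("train stage output missing; run 'train' first")
        pr.start()
        mc = SegModelConfig(**json.loads((tr.dir / "model_config.json").read_text()))
        mc = dataclasses.replace(mc, skip_taps=tuple(mc.skip_taps) if mc.skip_taps else None)
        model = build_model(mc, seed=cfg.train.seed)
        with np.load(tr.dir / "checkpoint.npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        for s in subs:
            pred = predict_masks(model, s, crop)
            np.save(pr.dir / f"{s.subject_id}.npy", pred)
        pr.finish()
        status["predict"] = "run"
    else:
        status["predict"] = "skipped" if "predict" in cfg.stages else "not-selected"

    # ---- quantify ---------------------------------------------------------
    qn = _Stage(
        "quantify", out, {"up": (dv.hash, pr.hash)},
        upstream_ran=status.get("derive") == "run" or status.get("predict") == "run",
    )
    if "quantify" in cfg.stages and not qn.fresh():
        subs, man = _load_cohort()
        qn.start()
        predicted = {}
        for s in subs:
            p = pr.dir / f"{s.subject_id}.npy"
            if p.exists():
                predicted[s.subject_id] = np.load(p)
        report = cohort_eh_report(subs, predicted or None)
        agreement = None
        if predicted:
            paired = report.dropna(subset=["pred_ratio"])
            if len(paired) >= 3:
                blocks = agreement_report(
                    paired["gt_ratio"], paired["pred_ratio"], paired["organ_type"]
                )
                agreement = {
                    name: {
                        "n": st.n_pairs, "icc": st.icc, "icc_ci": list(st.icc_ci),
                        "pearson_r": st.pearson_r,
                        "bland_altman": [st.bland_altman.mean_diff,
                                         st.bland_altman.loa_lower,
                                         st.bland_altman.loa_upper],
                        "insufficient": st.insufficient,
                    }
                    for name, st in blocks.items()
                }
        run_info = {"config_hash": qn.hash, "seed": cfg.seed, "version": __version__}
        write_outputs(report, qn.dir, run_info=run_info)
        if agreement is not None:
            (qn.dir / "agreement.json").write_text(json.dumps(agreement, indent=2))
        qn.finish()
        status["quantify"] = "run"
        result["report"] = report
    else:
        status["quantify"] = "skipped" if "quantify" in cfg.stages else "not-selected"
        if (qn.dir / "eh_report.csv").exists():
            result["report"] = pd.read_csv(qn.dir / "eh_report.csv")
    return result
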