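"""EH-ratio computation and rater-vs-model agreement statistics.

The endolymphatic-hydrops (EH) ratio of an organ is the fraction of pixels
with strictly negative HYDROPS-Mi2 value inside the organ's segmented
region — negative signal marks endolymph (non-enhanced fluid), positive
marks Gd-enhanced perilymph. Zero-valued pixels count as non-endolymph.

Agreement between two series of ratios (e.g. physician ground truth vs
model prediction) is summarized the way method-comparison studies do:
single-score two-way intraclass correlation (absolute agreement by
default, consistency as an option), Pearson correlation, and Bland-Altman
limits of agreement (mean difference +- 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imageops import compute_hydrops, compute_hydrops_mi2
from .stack import LABEL_NAMES, ORGAN_LABELS, ORGAN_TYPE_OF_LABEL, SubjectStack


class EmptyMaskError(ValueError):
    """The EH ratio is undefined on an empty segmentation mask."""


class DegenerateDataError(ValueError):
    """Agreement statistics are undefined when total variance is zero."""


@dataclass(frozen=True)
class EHRatio:
    ratio: float
    negative_pixels: int
    total_pixels: int


def eh_ratio(hydrops_mi2: np.ndarray, organ_mask: np.ndarray) -> EHRatio:
    """Pixels with negative value inside the mask / all pixels inside the mask.

    ``hydrops_mi2`` is the signed derived image (patch, slice or stack);
    ``organ_mask`` a boolean array of the same shape. The ratio depends only
    on signs, so it is invariant to any strictly positive rescaling.
    """
    img = np.asarray(hydrops_mi2)
    mask = np.asarray(organ_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    total = int(mask.sum())
    if total == 0:
        raise EmptyMaskError("EH ratio is undefined for an empty segmentation mask")
    negative = int((img[mask] < 0).sum())
    return EHRatio(ratio=negative / total, negative_pixels=negative, total_pixels=total)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltman:
    """Limits of agreement for paired measurements: mean(d) +- 1.96 SD(d), d = a-b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("bland_altman needs >= 2 aligned pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=md,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )


def icc_single_two_way(
    a: Sequence[float],
    b: Sequence[float],
    kind: Literal["absolute", "consistency"] = "absolute",
) -> Tuple[float, Tuple[float, float]]:
    """Single-score two-way intraclass correlation between two raters.

    ``absolute`` is the two-way random-effects, absolute-agreement,
    single-measurement ICC; ``consistency`` the two-way mixed consistency
    variant. Returns ``(icc, (ci_low, ci_high))`` with a 95% confidence
    interval. Raises :class:`DegenerateDataError` when the data carry no
    variance to correlate.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("icc needs >= 3 aligned pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("icc needs finite values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateDataError("zero total variance: ICC undefined")

    import pingouin as pg

    n = a.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([a, b]),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes the ANOVA F ratio infinite; the ICC itself
        # is still well-defined (1.0)
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    wanted = ("ICC2", "ICC(A,1)") if kind == "absolute" else ("ICC3", "ICC(C,1)")
    key = next(k for k in wanted if k in table.index)
    row = table.loc[key]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci = tuple(float(v) for v in row[ci_col])
    if not np.isfinite(icc):
        raise DegenerateDataError("ICC is undefined for these data")
    return icc, ci


@dataclass
class AgreementStats:
    """One block of agreement statistics between two ratio series."""

    n_pairs: int
    icc: float
    icc_ci: Tuple[float, float]
    pearson_r: float
    bland_altman: BlandAltman
    insufficient: bool = False


def _stats_block(gt: np.ndarray, pred: np.ndarray,
                 icc_kind: str = "absolute") -> AgreementStats:
    from scipy.stats import pearsonr

    icc, ci = icc_single_two_way(gt, pred, kind=icc_kind)
    r = float(pearsonr(gt, pred).statistic)
    return AgreementStats(
        n_pairs=gt.size, icc=icc, icc_ci=ci, pearson_r=r,
        bland_altman=bland_altman(gt, pred),
    )


def agreement_report(
    gt_ratios: Sequence[float],
    pred_ratios: Sequence[float],
    organ_types: Sequence[str],
    icc_kind: Literal["absolute", "consistency"] = "absolute",
) -> Dict[str, AgreementStats]:
    """Agreement blocks: overall, cochlea-only and vestibule-only.

    ``organ_types`` labels each pair ``"cochlea"`` or ``"vestibule"``.
    A block with fewer than 3 pairs is flagged insufficient rather than
    computed.
    """
    gt = np.asarray(gt_ratios, dtype=np.float64)
    pred = np.asarray(pred_ratios, dtype=np.float64)
    types = np.asarray(organ_types)
    if not (gt.shape == pred.shape == types.shape):
        raise ValueError("gt, pred and organ_types must be aligned")
    out: Dict[str, AgreementStats] = {}
    for name, sel in (
        ("overall", np.ones_like(gt, dtype=bool)),
        ("cochlea", types == "cochlea"),
        ("vestibule", types == "vestibule"),
    ):
        if sel.sum() < 3:
            out[name] = AgreementStats(
                n_pairs=int(sel.sum()), icc=float("nan"), icc_ci=(float("nan"),) * 2,
                pearson_r=float("nan"),
                bland_altman=BlandAltman(float("nan"), float("nan"), float("nan")),
                insufficient=True,
            )
            continue
        out[name] = _stats_block(gt[sel], pred[sel], icc_kind)
    return out


def eh_report(
    stack: SubjectStack,
    predicted_masks: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-organ EH ratios for one subject, from its own derived images.

    HYDROPS and HYDROPS-Mi2 are recomputed from the subject's PPI/PEI/MRC
    stacks; the ratio is evaluated inside the ground-truth mask of each
    organ and, when ``predicted_masks`` is given, inside the predicted mask
    of the same class (reported as missing when the prediction is empty).
    """
    mi2 = compute_hydrops_mi2(compute_hydrops(stack.ppi, stack.pei), stack.mrc)
    rows = []
    for lab in ORGAN_LABELS:
        gt_mask = stack.masks == lab
        if not gt_mask.any():
            continue
        gt = eh_ratio(mi2, gt_mask)
        row = dict(
            subject_id=stack.subject_id,
            organ=LABEL_NAMES[lab],
            organ_type=ORGAN_TYPE_OF_LABEL[lab],
            label=lab,
            gt_total_pixels=gt.total_pixels,
            gt_negative_pixels=gt.negative_pixels,
            gt_ratio=gt.ratio,
            true_fraction=(stack.truth or {}).get(lab, np.nan),
        )
        if predicted_masks is not None:
            pm = predicted_masks == lab
            if pm.any():
                pr = eh_ratio(mi2, pm)
                row.update(
                    pred_total_pixels=pr.total_pixels,
                    pred_negative_pixels=pr.negative_pixels,
                    pred_ratio=pr.ratio,
                )
            else:  # empty prediction: missing, not zero
                row.update(
                    pred_total_pixels=0, pred_negative_pixels=0, pred_ratio=np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_eh_report(
    subjects: Sequence[SubjectStack],
    predicted: Optional[Dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Concatenated :func:`eh_report` over a cohort."""
    frames = [
        eh_report(s, (predicted or {}).get(s.subject_id)) for s in subjects
    ]
    return pd.concat(frames, ignore_index=True)
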