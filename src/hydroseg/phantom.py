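"""Synthetic inner-ear phantoms: MRC/PPI/PEI triples with known truth.

Clinical inner-ear MRI with hydrops-protocol sequences is IRB-restricted and
not publicly archived, so every downstream stage of this package is
validated on phantoms that reproduce the *statistical structure* the
pipeline relies on, not the anatomy:

* three co-registered stacks in which perilymph is bright on PPI and
  endolymph is bright on PEI, so ``PPI - PEI`` is negative exactly inside
  the endolymph before noise is added;
* four organ-shaped structures (left/right cochlea and vestibule) that sit
  inside the fixed 100x100 crop windows even after center jitter;
* a controllable true endolymph fraction per organ — the ground-truth EH
  ratio the quantification stage must recover;
* additive Gaussian noise and smooth 3-slice through-plane continuity.

The cochlea is rendered as nested annular arcs (a topological proxy for the
basal/middle/apical turns), the vestibule as an ellipse. The endolymph
subregion is carved out of each organ by thresholding a smooth random field
inside the organ at the quantile matching the requested fraction, so its
shape varies between subjects while its area is exact to one pixel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imageops import CropSpec
from .stack import LC, LV, ORGAN_LABELS, RC, RV, LABEL_NAMES, SubjectStack


class OrganSizingError(ValueError):
    """An organ template does not fit inside its crop window."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Intensities live on a 0-1000 scale so the standard 400/1000 display
    window is meaningful. ``endolymph_fraction`` may be a single float
    (applied to every organ) or a mapping from organ label to fraction; it
    is the true EH ratio the phantom encodes. ``center_jitter`` randomises
    organ centers by up to that many pixels per axis. ``visibility`` marks
    organs as obviously visible (drives the selective/full annotation split
    downstream); by default all four organs are visible.
    """

    crop: CropSpec = CropSpec()
    n_slices: int = 3
    endolymph_fraction: float | Mapping[int, float] = 0.35
    perilymph_intensity: float = 800.0
    endolymph_intensity: float = 800.0
    background_intensity: float = 100.0
    mrc_fluid_intensity: float = 900.0
    noise_sd: float = 20.0
    center_jitter: int = 3
    visibility: Mapping[int, bool] = field(
        default_factory=lambda: {lab: True for lab in ORGAN_LABELS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3 (through-plane triplets)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lab, f in self.fractions().items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"endolymph_fraction for {LABEL_NAMES[lab]} must be in [0,1], got {f}"
                )

    def fractions(self) -> Dict[int, float]:
        if isinstance(self.endolymph_fraction, Mapping):
            return {lab: float(self.endolymph_fraction[lab]) for lab in ORGAN_LABELS}
        return {lab: float(self.endolymph_fraction) for lab in ORGAN_LABELS}

    def scaled(self, factor: float) -> "PhantomSpec":
        """Spec with all geometry scaled by ``factor`` (desk-scale phantoms)."""
        return dataclasses.replace(
            self,
            crop=self.crop.scaled(factor),
            center_jitter=max(1, int(round(self.center_jitter * factor))),
        )


# Organ template geometry, in coordinates relative to a 100x100 window and
# scaled with the window. Margins keep every organ >= (jitter + 8) px away
# from the window border so shift-augmentation never truncates a mask.
_COCHLEA_CENTER = (40.0, 35.0)  # (row, col) / 100
_COCHLEA_RADII = ((10.0, 15.0, 0.0, 300.0), (5.0, 8.5, 0.0, 330.0), (0.0, 3.0, 0.0, 360.0))
_VESTIBULE_CENTER = (60.0, 65.0)
_VESTIBULE_AXES = (8.0, 11.0)  # (row semi-axis, col semi-axis)


def _organ_window_mask(
    organ_type: str, window: Tuple[int, int], center_offset: Tuple[float, float],
    radius_scale: float,
) -> np.ndarray:
    """Rasterize one organ inside a window, at a given through-plane radius scale."""
    h, w = window
    u = min(h, w) / 100.0
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    if organ_type == "cochlea":
        cy = _COCHLEA_CENTER[0] * u + center_offset[0]
        cx = _COCHLEA_CENTER[1] * u + center_offset[1]
        dr, dc = rr - cy, cc - cx
        dist = np.hypot(dr, dc)
        ang = np.degrees(np.arctan2(dr, dc)) % 360.0
        mask = np.zeros((h, w), dtype=bool)
        for r_in, r_out, a0, a1 in _COCHLEA_RADII:
            ring = (dist >= r_in * u * radius_scale) & (dist <= r_out * u * radius_scale)
            if a1 - a0 < 360.0:
                ring &= (ang >= a0) & (ang <= a1)
            mask |= ring
        return mask
    if organ_type == "vestibule":
        cy = _VESTIBULE_CENTER[0] * u + center_offset[0]
        cx = _VESTIBULE_CENTER[1] * u + center_offset[1]
        ar = _VESTIBULE_AXES[0] * u * radius_scale
        ac = _VESTIBULE_AXES[1] * u * radius_scale
        return ((rr - cy) / ar) ** 2 + ((cc - cx) / ac) ** 2 <= 1.0
    raise ValueError(f"unknown organ type {organ_type!r}")


def _slice_radius_profile(n_slices: int) -> np.ndarray:
    """Through-plane size modulation: largest at the central slice."""
    center = (n_slices - 1) / 2.0
    k = np.arange(n_slices)
    return 1.0 - 0.2 * np.abs(k - center) / max(center, 1.0)


_ORGAN_TYPE = {LC: "cochlea", RC: "cochlea", LV: "vestibule", RV: "vestibule"}
_ORGAN_SIDE = {LC: "left", LV: "left", RC: "right", RV: "right"}


def generate_subject(spec: PhantomSpec, subject_id: str = "phantom-000") -> SubjectStack:
    """Generate one synthetic subject; bit-reproducible given ``spec.seed``.

    Raises :class:`OrganSizingError` if an organ template (after jitter)
    touches its crop window border.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.crop.source_shape
    S = spec.n_slices
    shape = (S, H, W)
    profile = _slice_radius_profile(S)
    fractions = spec.fractions()

    masks = np.zeros(shape, dtype=np.uint8)
    endo = np.zeros(shape, dtype=bool)
    # smooth random field drives endolymph shape; sigma scales with window
    sigma = max(1.5, spec.crop.window[0] / 12.0)
    fld = gaussian_filter(rng.standard_normal(shape), sigma=(1.0, sigma, sigma))

    truth: Dict[int, float] = {}
    for lab in ORGAN_LABELS:
        jr, jc = rng.integers(-spec.center_jitter, spec.center_jitter + 1, size=2)
        r0, c0 = spec.crop.origin(_ORGAN_SIDE[lab])
        organ3d = np.zeros(shape, dtype=bool)
        for k in range(S):
            m = _organ_window_mask(
                _ORGAN_TYPE[lab], spec.crop.window, (float(jr), float(jc)), profile[k]
            )
            if not m.any():
                raise OrganSizingError(
                    f"{LABEL_NAMES[lab]} template left its crop window entirely "
                    f"(window {spec.crop.window}, jitter ({jr},{jc}))"
                )
            if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
                raise OrganSizingError(
                    f"{LABEL_NAMES[lab]} template touches its crop window border "
                    f"(window {spec.crop.window}, jitter ({jr},{jc}))"
                )
            organ3d[k, r0 : r0 + spec.crop.window[0], c0 : c0 + spec.crop.window[1]] = m
        if masks[organ3d].any():
            raise OrganSizingError(f"{LABEL_NAMES[lab]} overlaps another organ")
        masks[organ3d] = lab

        # endolymph subregion: lowest-field voxels inside the organ, count
        # rounded to the nearest pixel of the requested fraction
        area = int(organ3d.sum())
        n_endo = int(round(fractions[lab] * area))
        if n_endo > 0:
            idx = np.flatnonzero(organ3d.ravel())
            order = np.argsort(fld.ravel()[idx], kind="stable")
            sel = idx[order[:n_endo]]
            e = np.zeros(shape, dtype=bool).ravel()
            e[sel] = True
            endo |= e.reshape(shape)
        truth[lab] = n_endo / area

    organ = masks > 0
    peri = organ & ~endo

    mrc = np.full(shape, spec.background_intensity, dtype=np.float64)
    mrc[organ] = spec.mrc_fluid_intensity
    ppi = np.full(shape, spec.background_intensity, dtype=np.float64)
    ppi[peri] = spec.perilymph_intensity
    pei = np.full(shape, spec.background_intensity, dtype=np.float64)
    pei[endo] = spec.endolymph_intensity

    if spec.noise_sd > 0:
        for arr in (mrc, ppi, pei):
            arr += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(arr, 0.0, 1000.0, out=arr)

    return SubjectStack(
        subject_id=subject_id,
        mrc=mrc,
        ppi=ppi,
        pei=pei,
        masks=masks,
        truth=truth,
        meta={"spec_seed": spec.seed, "visibility": dict(spec.visibility)},
    )


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges over :class:`PhantomSpec` fields for a cohort.

    ``endolymph_fraction`` is sampled uniformly per organ per subject;
    ``noise_sd`` uniformly per subject. ``p_secondary_visible`` is the
    probability that the non-organ-of-interest organ on a side is flagged
    visible; ``p_fully_annotated`` the probability that a (subject, side)
    patch belongs to the fully-annotated pool rather than the selectively
    annotated pool.
    """

    endolymph_fraction: Tuple[float, float] = (0.1, 0.6)
    noise_sd: Tuple[float, float] = (20.0, 20.0)
    p_secondary_visible: float = 0.7
    p_fully_annotated: float = 0.3

    def __post_init__(self) -> None:
        for name in ("endolymph_fraction", "noise_sd"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec = PhantomSpec(),
    ranges: CohortRanges = CohortRanges(),
    seed: int = 0,
) -> Tuple[list[SubjectStack], pd.DataFrame]:
    """Generate ``n_subjects`` phantoms plus an annotation manifest.

    The manifest has one row per (subject, organ) with the organ's true
    endolymph fraction, its visibility flag, whether it is the side's organ
    of interest, and the side's annotation pool (``SA`` or ``FA``).
    Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectStack] = []
    rows = []
    for i in range(n_subjects):
        sid = f"phantom-{i:03d}"
        frac = {
            lab: float(rng.uniform(*ranges.endolymph_fraction)) for lab in ORGAN_LABELS
        }
        noise = float(rng.uniform(*ranges.noise_sd))
        # per side: pick the organ of interest; the other organ may be less visible
        vis: Dict[int, bool] = {}
        ooi: Dict[str, int] = {}
        pool: Dict[str, str] = {}
        for side, labs in (("left", (LC, LV)), ("right", (RC, RV))):
            chosen = int(rng.choice(labs))
            ooi[side] = chosen
            for lab in labs:
                vis[lab] = True if lab == chosen else bool(
                    rng.random() < ranges.p_secondary_visible
                )
            pool[side] = "FA" if rng.random() < ranges.p_fully_annotated else "SA"
        spec = dataclasses.replace(
            base_spec,
            endolymph_fraction=frac,
            noise_sd=noise,
            visibility=vis,
            seed=int(rng.integers(0, 2**31)),
        )
        stack = generate_subject(spec, subject_id=sid)
        stack.meta.update(
            organ_of_interest=ooi, annotation_pool=pool, cohort_index=i
        )
        subjects.append(stack)
        for lab in ORGAN_LABELS:
            side = _ORGAN_SIDE[lab]
            rows.append(
                dict(
                    subject_id=sid,
                    organ=LABEL_NAMES[lab],
                    label=lab,
                    side=side,
                    organ_type=_ORGAN_TYPE[lab],
                    true_fraction=stack.truth[lab],
                    requested_fraction=frac[lab],
                    visible=vis[lab],
                    organ_of_interest=(ooi[side] == lab),
                    annotation_pool=pool[side],
                    noise_sd=noise,
                )
            )
    return subjects, pd.DataFrame(rows)
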