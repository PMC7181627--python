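"""Deterministic image arithmetic and patch geometry.

The derived images at the heart of endolymphatic-hydrops (EH) quantification:

* ``HYDROPS = PPI - PEI`` — negative exactly where endolymph dominates,
  because endolymph is bright on the positive endolymph image (PEI) and dark
  on the positive perilymph image (PPI);
* ``HYDROPS-Mi2 = HYDROPS * MRC`` — the product with MR cisternography,
  which boosts contrast-to-noise without changing the sign pattern wherever
  MRC is positive.

Both are computed in a signed wide dtype; negative values must survive to
the EH-ratio stage, so nothing is clipped.

Patch geometry: the inner ears sit in two fixed 100x100 windows of the
384x324 frame, anchored at per-side reference points. The reference points
are interpreted, by default, as the window's top-left corner in (row, col)
order — the only reading under which both default windows fit inside the
frame with the full shift-augmentation slack; axis order and anchor are
configurable because the convention is not universal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

Side = Literal["left", "right"]


@dataclass(frozen=True)
class CropSpec:
    """Fixed-reference-point cropping geometry.

    ``left_ref``/``right_ref`` locate the per-side windows inside a
    ``source_shape`` frame. ``axis_order`` says whether the stored reference
    pairs read (row, col) or (col, row); ``anchor`` says whether they name
    the window's top-left corner or its center.
    """

    window: Tuple[int, int] = (100, 100)  # (rows, cols)
    left_ref: Tuple[int, int] = (215, 238)
    right_ref: Tuple[int, int] = (204, 92)
    source_shape: Tuple[int, int] = (324, 384)  # (rows, cols)
    axis_order: Literal["rowcol", "colrow"] = "rowcol"
    anchor: Literal["topleft", "center"] = "topleft"

    def origin(self, side: Side) -> Tuple[int, int]:
        """Top-left (row, col) of the side's window under this convention."""
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        ref = self.left_ref if side == "left" else self.right_ref
        r, c = ref if self.axis_order == "rowcol" else (ref[1], ref[0])
        if self.anchor == "center":
            r -= self.window[0] // 2
            c -= self.window[1] // 2
        return (r, c)

    def validate(self, slack: int = 0) -> None:
        """Raise if either window (expanded by ``slack`` px) leaves the frame."""
        H, W = self.source_shape
        h, w = self.window
        for side in ("left", "right"):
            r, c = self.origin(side)
            if r - slack < 0 or c - slack < 0 or r + h + slack > H or c + w + slack > W:
                raise ValueError(
                    f"{side} window [{r}:{r + h}, {c}:{c + w}] with slack {slack} "
                    f"does not fit inside source {self.source_shape}"
                )

    def scaled(self, factor: float) -> "CropSpec":
        """Geometry scaled by ``factor`` (used for desk-scale phantoms)."""

        def s(t: Tuple[int, int]) -> Tuple[int, int]:
            return (int(round(t[0] * factor)), int(round(t[1] * factor)))

        return CropSpec(
            window=s(self.window),
            left_ref=s(self.left_ref),
            right_ref=s(self.right_ref),
            source_shape=s(self.source_shape),
            axis_order=self.axis_order,
            anchor=self.anchor,
        )


@dataclass(frozen=True)
class WindowSetting:
    """Display window (level/width) mapping intensities to a display range."""

    level: float = 400.0
    width: float = 1000.0
    out_range: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


@dataclass
class Patch:
    """A cropped window with provenance of where it came from."""

    data: np.ndarray
    side: Side
    slice_index: int | None = None
    origin: Tuple[int, int] = (0, 0)  # (row, col) in the source frame
    shift: Tuple[int, int] = (0, 0)


def _check_same_shape(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")


def compute_hydrops(ppi: np.ndarray, pei: np.ndarray) -> np.ndarray:
    """Elementwise PPI - PEI in a signed representation (negatives preserved)."""
    ppi = np.asarray(ppi)
    pei = np.asarray(pei)
    _check_same_shape(ppi, pei, "compute_hydrops")
    if ppi.dtype.kind in "ui" and pei.dtype.kind in "ui":
        return ppi.astype(np.int64) - pei.astype(np.int64)
    return ppi.astype(np.float64) - pei.astype(np.float64)


def compute_hydrops_mi2(hydrops: np.ndarray, mrc: np.ndarray) -> np.ndarray:
    """Elementwise HYDROPS * MRC; sign follows HYDROPS wherever MRC > 0."""
    hydrops = np.asarray(hydrops)
    mrc = np.asarray(mrc)
    _check_same_shape(hydrops, mrc, "compute_hydrops_mi2")
    if np.any(np.asarray(mrc) < 0):
        raise ValueError("MRC intensities must be non-negative")
    if hydrops.dtype.kind in "iu" and mrc.dtype.kind in "iu":
        return hydrops.astype(np.int64) * mrc.astype(np.int64)
    return hydrops.astype(np.float64) * mrc.astype(np.float64)


def apply_window(image: np.ndarray, w: WindowSetting = WindowSetting()) -> np.ndarray:
    """Linear level/width display mapping, clipped outside the window.

    ``[level - width/2, level + width/2]`` maps onto ``out_range``;
    monotone non-decreasing in the input.
    """
    img = np.asarray(image, dtype=np.float64)
    lo = w.level - w.width / 2.0
    out_lo, out_hi = w.out_range
    scaled = (img - lo) / w.width * (out_hi - out_lo) + out_lo
    return np.clip(scaled, min(out_lo, out_hi), max(out_lo, out_hi))


def crop_patch(
    slice2d: np.ndarray,
    side: Side,
    spec: CropSpec = CropSpec(),
    shift: Tuple[int, int] = (0, 0),
    slice_index: int | None = None,
) -> Patch:
    """Crop the side's window (shifted by ``shift`` = (drow, dcol)) from a slice."""
    arr = np.asarray(slice2d)
    if arr.ndim != 2:
        raise ValueError(f"crop_patch expects a 2-D slice, got {arr.ndim}-D")
    h, w = spec.window
    r0, c0 = spec.origin(side)
    r0 += int(shift[0])
    c0 += int(shift[1])
    if r0 < 0 or c0 < 0 or r0 + h > arr.shape[0] or c0 + w > arr.shape[1]:
        raise ValueError(
            f"crop window [{r0}:{r0 + h}, {c0}:{c0 + w}] out of bounds for "
            f"slice shape {arr.shape}"
        )
    return Patch(
        data=arr[r0 : r0 + h, c0 : c0 + w].copy(),
        side=side,
        slice_index=slice_index,
        origin=(r0, c0),
        shift=(int(shift[0]), int(shift[1])),
    )


def embed_patch(target: np.ndarray, patch_data: np.ndarray, origin: Tuple[int, int]) -> None:
    """Write a patch back into a full-frame array at its crop origin (in place)."""
    h, w = patch_data.shape
    r0, c0 = origin
    if r0 < 0 or c0 < 0 or r0 + h > target.shape[0] or c0 + w > target.shape[1]:
        raise ValueError("patch does not fit in the target frame at its origin")
    target[r0 : r0 + h, c0 : c0 + w] = patch_data


def minmax01(patch: np.ndarray) -> np.ndarray:
    """Per-patch min-max normalization to [0, 1]; constant patches map to 0."""
    p = np.asarray(patch, dtype=np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)
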