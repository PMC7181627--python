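"""Dataset augmentation: flip, shift-recropping and brightness enumeration.

The augmented dataset is built once, deterministically, at dataset-build
time (epochs then see a fixed set). Three scales are supported, defined by
their exact multiplicities per original patch:

* ``low``      — flip x shift only:                      144 variants
* ``moderate`` — flip x shift x brightness step 10:    1,584 variants
* ``high``     — flip x shift x brightness step 1:    14,544 variants

144 decomposes as 2 flip states x 9 directional shift states x 8 sampled
offsets per state (shift magnitude bounded by 8 px in the Chebyshev norm);
this is the only decomposition consistent with the printed multiplicities
and the nine compass-plus-center shift states, but the sampling detail is
inferred, so it stays configurable. Brightness offsets span -50..50 at the
scale's step (always including 0) and are applied to the image only, after
which intensities are clipped to the valid range; geometric transforms are
applied identically to image and mask, and a horizontal flip swaps the
left/right class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .imageops import CropSpec, Side, crop_patch
from .stack import FLIP_LABEL_SWAP

Scale = Literal["low", "moderate", "high"]

#: brightness step per augmentation scale (None = no brightness augmentation)
SCALE_BRIGHTNESS_STEP = {"low": None, "moderate": 10, "high": 1}

# 9 directional states: center + 8 compass directions, as (sign_row, sign_col)
_DIRECTIONS: Tuple[Tuple[int, int], ...] = (
    (0, 0),
    (-1, 0), (1, 0), (0, -1), (0, 1),
    (-1, -1), (-1, 1), (1, -1), (1, 1),
)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Enumeration parameters realizing the three augmentation scales."""

    flip_states: Tuple[bool, ...] = (False, True)
    shift_range: int = 8
    shift_samples_per_direction: int = 8
    brightness_range: int = 50
    intensity_max: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_samples_per_direction < 1:
            raise ValueError("shift_samples_per_direction must be >= 1")
        if self.shift_range < 1:
            raise ValueError("shift_range must be >= 1")


def enumerate_brightness_offsets(
    brightness_range: int = 50, step: Optional[int] = None
) -> List[int]:
    """Brightness offsets for one scale: symmetric about 0 and including 0.

    ``step=None`` (low augmentation) yields ``[0]``; step ``s`` yields
    ``-range, -range+s, ..., range``.
    """
    if step is None:
        return [0]
    if step <= 0:
        raise ValueError("brightness step must be > 0")
    if brightness_range % step != 0:
        raise ValueError(
            f"step {step} must divide brightness_range {brightness_range}"
        )
    return list(range(-brightness_range, brightness_range + 1, step))


def enumerate_geometric_states(
    policy: AugmentationPolicy = AugmentationPolicy(),
) -> List[Tuple[bool, Tuple[int, int]]]:
    """The (flip, shift-offset) list for one original patch.

    Count = |flip states| x 9 directions x samples-per-direction (= 144 at
    defaults). Offsets are bounded by ``shift_range`` in the Chebyshev norm;
    the center state always contributes the zero offset. Deterministic given
    ``policy.seed``.
    """
    rng = np.random.default_rng(policy.seed)
    states: List[Tuple[bool, Tuple[int, int]]] = []
    for flip in policy.flip_states:
        for sr, sc in _DIRECTIONS:
            for _ in range(policy.shift_samples_per_direction):
                dr = 0 if sr == 0 else sr * int(rng.integers(1, policy.shift_range + 1))
                dc = 0 if sc == 0 else sc * int(rng.integers(1, policy.shift_range + 1))
                states.append((bool(flip), (dr, dc)))
    return states


@dataclass
class AugmentedPatches:
    """The augmented set for one original patch, as a lazy sequence.

    Variant ``i`` pairs geometric state ``i % n_geometric`` with brightness
    offset ``i // n_geometric``; the geometric variants are stored once and
    the (mask-preserving) brightness shift is applied on access, so the set
    is cheap to build at any scale while indexing stays exact. ``flips``,
    ``shifts`` and ``brightness(i)`` expose each variant's provenance.
    """

    geo_images: np.ndarray  # (n_geo, h, w) float32
    geo_masks: np.ndarray  # (n_geo, h, w) uint8
    offsets: np.ndarray  # brightness offsets
    intensity_max: float
    flips: np.ndarray
    shifts: np.ndarray

    def __len__(self) -> int:
        return self.geo_images.shape[0] * self.offsets.size

    def brightness(self, i: int) -> int:
        return int(self.offsets[i // self.geo_images.shape[0]])

    def __getitem__(self, i: int) -> Tuple[np.ndarray, np.ndarray]:
        n_geo = self.geo_images.shape[0]
        if not -len(self) <= i < len(self):
            raise IndexError(i)
        i %= len(self)
        g, b = i % n_geo, i // n_geo
        img = np.clip(
            self.geo_images[g] + np.float32(self.offsets[b]), 0.0, self.intensity_max
        )
        return img, self.geo_masks[g]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def _flip_mask_labels(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for src, dst in FLIP_LABEL_SWAP.items():
        out[mask == src] = dst
    return out


def augment_patch(
    image_slice: np.ndarray,
    mask_slice: np.ndarray,
    side: Side,
    crop: CropSpec,
    policy: AugmentationPolicy = AugmentationPolicy(),
    scale: Scale = "low",
) -> AugmentedPatches:
    """Build every augmentation variant of one side's patch on one slice.

    Shift states re-crop the window from the full ``image_slice`` /
    ``mask_slice`` (so the window needs ``shift_range`` slack inside the
    frame); flips mirror image and mask together and side-swap the mask
    labels; brightness offsets shift the image intensities only, clipped to
    ``[0, intensity_max]``.
    """
    if image_slice.shape != mask_slice.shape:
        raise ValueError("image and mask slices must share shape")
    crop.validate(slack=policy.shift_range)  # insufficient slack -> error here
    geo = enumerate_geometric_states(policy)
    offsets = enumerate_brightness_offsets(
        policy.brightness_range, SCALE_BRIGHTNESS_STEP[scale]
    )

    h, w = crop.window
    imgs = np.empty((len(geo), h, w), dtype=np.float32)
    msks = np.empty((len(geo), h, w), dtype=np.uint8)
    for i, (flip, shift) in enumerate(geo):
        ip = crop_patch(image_slice, side, crop, shift=shift).data
        mp = crop_patch(mask_slice, side, crop, shift=shift).data
        if flip:
            ip = np.fliplr(ip)
            mp = _flip_mask_labels(np.fliplr(mp))
        imgs[i] = ip
        msks[i] = mp

    return AugmentedPatches(
        geo_images=imgs,
        geo_masks=msks,
        offsets=np.asarray(offsets, dtype=np.int16),
        intensity_max=policy.intensity_max,
        flips=np.array([f for f, _ in geo], dtype=bool),
        shifts=np.array([s for _, s in geo], dtype=np.int16),
    )


def expected_count(policy: AugmentationPolicy, scale: Scale) -> int:
    """Multiplicity per original patch for a scale (144 / 1,584 / 14,544)."""
    n_geo = len(policy.flip_states) * len(_DIRECTIONS) * policy.shift_samples_per_direction
    n_b = len(
        enumerate_brightness_offsets(policy.brightness_range, SCALE_BRIGHTNESS_STEP[scale])
    )
    return n_geo * n_b
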