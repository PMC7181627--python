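"""Shared containers: the per-subject image stack and the class alphabet.

A subject is represented by three co-registered grayscale stacks — MR
cisternography (MRC), positive perilymph image (PPI) and positive endolymph
image (PEI) — plus an optional per-slice label mask over five classes:
background, left/right cochlea and left/right vestibule.

Array convention (repo-wide): arrays are indexed ``(slice, row, col)``,
0-based, origin at the top-left of each slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

# Five-class label alphabet.
BACKGROUND = 0
LC = 1  # left cochlea
LV = 2  # left vestibule
RC = 3  # right cochlea
RV = 4  # right vestibule

ORGAN_LABELS = (LC, LV, RC, RV)
LABEL_NAMES = {BACKGROUND: "background", LC: "LC", LV: "LV", RC: "RC", RV: "RV"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: horizontal flip swaps anatomical sides: LC<->RC, LV<->RV
FLIP_LABEL_SWAP = {BACKGROUND: BACKGROUND, LC: RC, RC: LC, LV: RV, RV: LV}

SIDE_OF_LABEL = {LC: "left", LV: "left", RC: "right", RV: "right"}
ORGAN_TYPE_OF_LABEL = {LC: "cochlea", RC: "cochlea", LV: "vestibule", RV: "vestibule"}


@dataclass
class SubjectStack:
    """Aligned MRC/PPI/PEI stacks (slice x row x col) for one subject.

    ``masks`` is an optional integer label stack over the five-class
    alphabet; ``truth`` optionally records the true endolymph fraction per
    organ label (known for phantoms, unknown for real data).
    """

    subject_id: str
    mrc: np.ndarray
    ppi: np.ndarray
    pei: np.ndarray
    masks: Optional[np.ndarray] = None
    truth: Optional[Mapping[int, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = np.asarray(self.mrc).shape
        for name in ("mrc", "ppi", "pei"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 3:
                raise ValueError(f"{name} must be 3-D (slice, row, col); got {arr.ndim}-D")
            if arr.shape != shape:
                raise ValueError(
                    f"sequence shapes differ: mrc {shape} vs {name} {arr.shape}"
                )
            setattr(self, name, arr)
        if self.masks is not None:
            m = np.asarray(self.masks)
            if m.shape != shape:
                raise ValueError(f"mask shape {m.shape} != image shape {shape}")
            bad = set(np.unique(m)) - set(LABEL_NAMES)
            if bad:
                raise ValueError(f"mask contains labels outside the alphabet: {sorted(bad)}")
            self.masks = m.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mrc.shape

    @property
    def n_slices(self) -> int:
        return self.mrc.shape[0]
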