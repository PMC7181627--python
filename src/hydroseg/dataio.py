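"""Reading and writing image stacks, masks and reports.

Supported stack formats: a DICOM series directory, a NIfTI file
(``.nii``/``.nii.gz``), or a directory of per-slice PNG/TIFF files.
Integer images and label masks round-trip losslessly in every format.
Signed derived images (HYDROPS, HYDROPS-Mi2) are written as float NIfTI,
since PNG cannot hold negatives.

Arrays follow the repo-wide (slice, row, col) convention with the origin at
the top-left of each slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .stack import SubjectStack

_SEQUENCES = ("mrc", "ppi", "pei")


class ManifestError(ValueError):
    """A stack manifest is incomplete or inconsistent."""


class AlignmentError(ValueError):
    """Sequences of one subject do not share shape/slice count."""


@dataclass
class StackManifest:
    """Where one subject's sequences (and optional masks) live on disk.

    Each path may be a NIfTI file, a DICOM series directory, or a directory
    of per-slice PNG/TIFF images. ``slice_order`` orders directory slices:
    ``"name"`` sorts by filename, ``"instance"`` by DICOM InstanceNumber.
    """

    subject_id: str
    mrc: Path
    ppi: Path
    pei: Path
    masks: Optional[Path] = None
    slice_order: Literal["name", "instance"] = "name"

    def __post_init__(self) -> None:
        for seq in _SEQUENCES:
            p = getattr(self, seq)
            if p is None:
                raise ManifestError(f"manifest for {self.subject_id} is missing {seq}")
            setattr(self, seq, Path(p))
        if self.masks is not None:
            self.masks = Path(self.masks)


def _read_png_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ManifestError(f"no PNG/TIFF slices in {path}")
    slices = [np.asarray(Image.open(f)) for f in files]
    return np.stack(slices, axis=0)


def _read_dicom_dir(path: Path, order: str) -> np.ndarray:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    ds = [pydicom.dcmread(f) for f in files if f.is_file()]
    if not ds:
        raise ManifestError(f"no DICOM files in {path}")
    if order == "instance":
        ds.sort(key=lambda d: int(d.InstanceNumber))
    else:
        pass  # already filename-sorted
    return np.stack([d.pixel_array for d in ds], axis=0)


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    # stored (row, col, slice) -> (slice, row, col)
    return np.ascontiguousarray(np.moveaxis(data, -1, 0))


def _read_stack_path(path: Path, order: str) -> np.ndarray:
    if path.is_dir():
        entries = list(path.iterdir())
        if any(p.suffix.lower() in (".png", ".tif", ".tiff") for p in entries):
            return _read_png_dir(path)
        return _read_dicom_dir(path, order)
    if path.suffixes and path.suffixes[-1] in (".nii",) or path.name.endswith(
        (".nii", ".nii.gz")
    ):
        return _read_nifti(path)
    raise ManifestError(f"unrecognised stack path {path}")


def read_stack(manifest: StackManifest) -> SubjectStack:
    """Assemble a :class:`SubjectStack` from a manifest.

    Raises :class:`AlignmentError` if the three sequences (or the masks) do
    not share shape.
    """
    arrays: Dict[str, np.ndarray] = {
        seq: _read_stack_path(getattr(manifest, seq), manifest.slice_order)
        for seq in _SEQUENCES
    }
    shapes = {seq: a.shape for seq, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise AlignmentError(f"sequence shapes differ for {manifest.subject_id}: {shapes}")
    masks = None
    if manifest.masks is not None:
        masks = _read_stack_path(manifest.masks, manifest.slice_order)
        if masks.shape != arrays["mrc"].shape:
            raise AlignmentError(
                f"mask shape {masks.shape} != image shape {arrays['mrc'].shape}"
            )
    return SubjectStack(subject_id=manifest.subject_id, masks=masks, **arrays)


def _write_png_dir(arr: np.ndarray, path: Path, dtype: np.dtype) -> None:
    path.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(arr)
    for k in range(arr.shape[0]):
        sl = arr[k].astype(dtype)
        Image.fromarray(sl).save(path / f"slice_{k:03d}.png")


def _write_nifti(arr: np.ndarray, path: Path) -> None:
    import nibabel as nib

    data = np.moveaxis(np.asarray(arr), 0, -1)  # (slice,row,col) -> (row,col,slice)
    if data.dtype == np.int64:  # NIfTI-1 has no 64-bit int type
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))


def write_subject(
    stack: SubjectStack,
    out_dir: Path,
    fmt: Literal["png", "nifti"] = "png",
    intensity_dtype: np.dtype = np.uint16,
) -> StackManifest:
    """Write one subject's sequences (+ masks) and return a manifest for them.

    PNG output stores intensities as 16-bit integers (rounded if the arrays
    are float) and masks as 8-bit indexed PNG; NIfTI stores float64.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for seq in _SEQUENCES:
        arr = getattr(stack, seq)
        if fmt == "png":
            p = out_dir / seq
            _write_png_dir(np.rint(arr), p, np.dtype(intensity_dtype))
        else:
            p = out_dir / f"{seq}.nii.gz"
            _write_nifti(arr, p)
        paths[seq] = p
    masks_path = None
    if stack.masks is not None:
        if fmt == "png":
            masks_path = out_dir / "masks"
            _write_png_dir(stack.masks, masks_path, np.dtype(np.uint8))
        else:
            masks_path = out_dir / "masks.nii.gz"
            _write_nifti(stack.masks.astype(np.uint8), masks_path)
    if stack.truth is not None:
        (out_dir / "truth.json").write_text(
            json.dumps({str(k): v for k, v in stack.truth.items()}, indent=2)
        )
    return StackManifest(
        subject_id=stack.subject_id, masks=masks_path, **paths
    )


def load_subject(subject_dir: Path, slice_order: str = "name") -> SubjectStack:
    """Read back a subject written by :func:`write_subject`.

    Restores the truth table (true endolymph fractions) if present.
    """
    subject_dir = Path(subject_dir)
    paths = {}
    for seq in _SEQUENCES:
        png = subject_dir / seq
        nii = subject_dir / f"{seq}.nii.gz"
        paths[seq] = png if png.is_dir() else nii
    masks = None
    if (subject_dir / "masks").is_dir():
        masks = subject_dir / "masks"
    elif (subject_dir / "masks.nii.gz").exists():
        masks = subject_dir / "masks.nii.gz"
    manifest = StackManifest(
        subject_id=subject_dir.name, masks=masks, slice_order=slice_order, **paths
    )
    stack = read_stack(manifest)
    truth_path = subject_dir / "truth.json"
    if truth_path.exists():
        stack.truth = {int(k): float(v) for k, v in json.loads(truth_path.read_text()).items()}
    return stack


def write_outputs(
    report: pd.DataFrame,
    out_dir: Path,
    masks: Optional[Dict[str, np.ndarray]] = None,
    run_info: Optional[dict] = None,
) -> Dict[str, Path]:
    """Write an EH-ratio report (CSV + JSON), predicted masks and a run log.

    ``masks`` maps subject id to a predicted label stack (written as
    per-slice indexed PNG). Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    csv_path = out_dir / "eh_report.csv"
    report.to_csv(csv_path, index=False)
    paths["report_csv"] = csv_path
    json_path = out_dir / "eh_report.json"
    json_path.write_text(report.to_json(orient="records", indent=2))
    paths["report_json"] = json_path
    if masks:
        for sid, arr in masks.items():
            p = out_dir / "predicted_masks" / sid
            _write_png_dir(np.asarray(arr), p, np.dtype(np.uint8))
        paths["predicted_masks"] = out_dir / "predicted_masks"
    if run_info is not None:
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(run_info, indent=2, default=str))
        paths["run_log"] = log_path
    return paths


def read_report(out_dir: Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_outputs`."""
    return pd.read_csv(Path(out_dir) / "eh_report.csv")
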