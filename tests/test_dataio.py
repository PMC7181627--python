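"""Round-trips and error handling for stacks, masks and reports."""

import numpy as np
import pandas as pd
import pytest

import hydroseg as hs
from hydroseg.dataio import (
    AlignmentError,
    ManifestError,
    StackManifest,
    load_subject,
    read_report,
    read_stack,
    write_outputs,
    write_subject,
)


@pytest.fixture(scope="module")
def noisy_subject():
    spec = hs.PhantomSpec(noise_sd=17.3, seed=2).scaled(0.24)
    return hs.generate_subject(spec, "rt-subject")


class TestPngRoundTrip:
    def test_bit_identical_integer_round_trip(self, noisy_subject, tmp_path):
        manifest = write_subject(noisy_subject, tmp_path / "s", fmt="png")
        back = read_stack(manifest)
        for seq in ("mrc", "ppi", "pei"):
            assert np.array_equal(
                np.asarray(getattr(back, seq)), np.rint(getattr(noisy_subject, seq))
            )

    def test_mask_label_alphabet_preserved(self, noisy_subject, tmp_path):
        write_subject(noisy_subject, tmp_path / "s", fmt="png")
        back = load_subject(tmp_path / "s")
        assert np.array_equal(back.masks, noisy_subject.masks)
        assert set(np.unique(back.masks)) == set(np.unique(noisy_subject.masks))

    def test_truth_restored(self, noisy_subject, tmp_path):
        write_subject(noisy_subject, tmp_path / "s", fmt="png")
        back = load_subject(tmp_path / "s")
        assert back.truth == noisy_subject.truth


def test_nifti_round_trip_is_lossless(noisy_subject, tmp_path):
    write_subject(noisy_subject, tmp_path / "s", fmt="nifti")
    back = load_subject(tmp_path / "s")
    for seq in ("mrc", "ppi", "pei"):
        assert np.array_equal(np.asarray(getattr(back, seq)),
                              np.asarray(getattr(noisy_subject, seq)))
    assert np.array_equal(back.masks, noisy_subject.masks)


def test_slice_count_mismatch_raises_alignment_error(noisy_subject, tmp_path):
    manifest = write_subject(noisy_subject, tmp_path / "s", fmt="png")
    # drop one PPI slice
    slices = sorted((tmp_path / "s" / "ppi").glob("*.png"))
    slices[-1].unlink()
    with pytest.raises(AlignmentError):
        read_stack(manifest)


def test_missing_sequence_raises_manifest_error(tmp_path):
    with pytest.raises(ManifestError):
        StackManifest(subject_id="x", mrc=tmp_path, ppi=None, pei=tmp_path)


def _write_dicom_slice(path, arr, instance):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import (
        ExplicitVRLittleEndian,
        SecondaryCaptureImageStorage,
        generate_uid,
    )

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.InstanceNumber = instance
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsStored = 16
    ds.PixelData = arr.astype("<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_sorted_by_instance_number(noisy_subject, tmp_path):
    """Slices written with shuffled filenames re-sort by InstanceNumber."""
    arr = np.rint(noisy_subject.mrc).astype(np.uint16)
    for seq in ("mrc", "ppi", "pei"):
        d = tmp_path / seq
        d.mkdir()
        src = np.rint(getattr(noisy_subject, seq)).astype(np.uint16)
        # filename order is the reverse of instance order
        for fname, inst in (("a.dcm", 3), ("b.dcm", 2), ("c.dcm", 1)):
            _write_dicom_slice(d / fname, src[inst - 1], inst)
    manifest = StackManifest(
        subject_id="dcm", mrc=tmp_path / "mrc", ppi=tmp_path / "ppi",
        pei=tmp_path / "pei", slice_order="instance",
    )
    back = read_stack(manifest)
    assert np.array_equal(back.mrc, arr)


class TestReportOutputs:
    @pytest.fixture()
    def report(self):
        return pd.DataFrame(
            {
                "subject_id": ["s0", "s0"],
                "organ": ["LC", "RV"],
                "gt_total_pixels": [63, 37],
                "gt_negative_pixels": [21, 9],
                "gt_ratio": [21 / 63, 9 / 37],
            }
        )

    def test_csv_one_row_per_organ_and_round_trip(self, report, tmp_path):
        paths = write_outputs(report, tmp_path, run_info={"seed": 1})
        back = read_report(tmp_path)
        assert len(back) == 2
        pd.testing.assert_frame_equal(back, report)
        assert paths["report_json"].exists()
        assert paths["run_log"].exists()

    def test_predicted_mask_round_trip_preserves_alphabet(self, report, tmp_path, noisy_subject):
        write_outputs(report, tmp_path, masks={"s0": noisy_subject.masks})
        from PIL import Image

        files = sorted((tmp_path / "predicted_masks" / "s0").glob("*.png"))
        back = np.stack([np.asarray(Image.open(f)) for f in files])
        assert set(np.unique(back)) == set(np.unique(noisy_subject.masks))
        assert np.array_equal(back, noisy_subject.masks)
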