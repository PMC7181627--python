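"""Image arithmetic, display windowing and fixed-reference cropping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import hydroseg as hs
from hydroseg.imageops import CropSpec, WindowSetting, embed_patch, minmax01


class TestHydrops:
    def test_equal_inputs_give_zero(self):
        x = np.full((5, 6), 123.0)
        assert (hs.compute_hydrops(x, x) == 0).all()

    def test_strictly_negative_when_pei_dominates(self):
        ppi = np.zeros((4, 4))
        pei = np.full((4, 4), 7.0)
        assert (hs.compute_hydrops(ppi, pei) < 0).all()

    def test_integer_inputs_keep_signed_dtype(self):
        ppi = np.zeros((3, 3), dtype=np.uint16)
        pei = np.full((3, 3), 9, dtype=np.uint16)
        out = hs.compute_hydrops(ppi, pei)
        assert out.dtype == np.int64
        assert (out == -9).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hs.compute_hydrops(np.zeros((2, 2)), np.zeros((3, 3)))


class TestHydropsMi2:
    def test_unit_mrc_is_identity(self):
        h = np.array([[-2.0, 3.0], [0.0, -1.0]])
        assert np.array_equal(hs.compute_hydrops_mi2(h, np.ones_like(h)), h)

    def test_zero_mrc_zeroes_everything(self):
        h = np.array([[-2.0, 3.0]])
        assert (hs.compute_hydrops_mi2(h, np.zeros_like(h)) == 0).all()

    def test_sign_pattern_preserved_where_mrc_positive(self):
        rng = np.random.default_rng(5)
        h = rng.integers(-50, 50, (8, 9))
        m = rng.integers(0, 10, (8, 9))
        out = hs.compute_hydrops_mi2(h, m)
        pos = m > 0
        assert np.array_equal(np.sign(out[pos]), np.sign(h[pos]))

    def test_negative_mrc_rejected(self):
        with pytest.raises(ValueError):
            hs.compute_hydrops_mi2(np.zeros((2, 2)), np.full((2, 2), -1.0))

    def test_antisymmetric_in_ppi_pei(self):
        rng = np.random.default_rng(8)
        ppi, pei = rng.random((2, 6, 7)) * 1000
        mrc = rng.random((6, 7)) * 1000
        a = hs.compute_hydrops_mi2(hs.compute_hydrops(ppi, pei), mrc)
        b = hs.compute_hydrops_mi2(hs.compute_hydrops(pei, ppi), mrc)
        assert np.allclose(a, -b)


class TestWindowing:
    def test_level_maps_to_display_midpoint(self):
        out = hs.apply_window(np.array([[400.0]]), WindowSetting())
        assert out[0, 0] == pytest.approx(0.5)

    def test_clipping_at_window_edges(self):
        w = WindowSetting()  # window [-100, 900]
        img = np.array([[-100.0, -500.0, 900.0, 1500.0]])
        out = hs.apply_window(img, w)
        assert np.allclose(out, [[0.0, 0.0, 1.0, 1.0]])

    def test_ramp_matches_closed_form(self):
        w = WindowSetting(level=400, width=1000)
        x = np.linspace(-200, 1100, 131)
        expected = np.clip((x - (400 - 500)) / 1000, 0, 1)
        assert np.allclose(hs.apply_window(x, w), expected)

    @given(
        arrays(np.float64, (12,), elements=st.floats(-2000, 2000)),
    )
    def test_monotone_non_decreasing(self, vals):
        order = np.argsort(vals)
        out = hs.apply_window(vals, WindowSetting())
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            WindowSetting(width=0)


class TestCropping:
    def test_default_windows_fit_with_shift_slack(self):
        CropSpec().validate(slack=8)

    def test_patch_shape_and_determinism(self):
        img = np.arange(324 * 384, dtype=float).reshape(324, 384)
        a = hs.crop_patch(img, "left")
        b = hs.crop_patch(img, "left")
        assert a.data.shape == (100, 100)
        assert np.array_equal(a.data, b.data)
        assert a.origin == (215, 238)

    def test_patch_pixels_match_source_indexing(self):
        rng = np.random.default_rng(0)
        img = rng.random((324, 384))
        spec = CropSpec()
        for side in ("left", "right"):
            p = hs.crop_patch(img, side, spec, shift=(3, -2))
            r0, c0 = p.origin
            for _ in range(20):
                i, j = rng.integers(0, 100, 2)
                assert p.data[i, j] == img[r0 + i, c0 + j]

    def test_out_of_bounds_shift_rejected(self):
        img = np.zeros((324, 384))
        with pytest.raises(ValueError):
            hs.crop_patch(img, "left", shift=(50, 50))

    def test_axis_order_and_anchor_options(self):
        img = np.zeros((324, 384))
        spec = CropSpec(axis_order="colrow", anchor="center", left_ref=(215, 238))
        with pytest.raises(ValueError):
            spec.origin("up")
        p = hs.crop_patch(img, "left", spec)
        assert p.origin == (238 - 50, 215 - 50)

    def test_embed_crop_round_trip(self):
        rng = np.random.default_rng(1)
        frame = np.zeros((324, 384))
        patch = rng.random((100, 100))
        spec = CropSpec()
        embed_patch(frame, patch, spec.origin("right"))
        again = hs.crop_patch(frame, "right", spec)
        assert np.array_equal(again.data, patch)


def test_minmax_normalization():
    x = np.array([[2.0, 4.0], [6.0, 2.0]])
    out = minmax01(x)
    assert out.min() == 0.0 and out.max() == 1.0
    assert (minmax01(np.full((3, 3), 5.0)) == 0).all()


def test_noiseless_phantom_negative_set_equals_endolymph(small_subject):
    """{HYDROPS-Mi2 < 0} inside the organ masks is exactly the endolymph."""
    mi2 = hs.compute_hydrops_mi2(
        hs.compute_hydrops(small_subject.ppi, small_subject.pei), small_subject.mrc
    )
    neg_in_organ = (mi2 < 0) & (small_subject.masks > 0)
    raw_neg = (small_subject.ppi - small_subject.pei) < 0
    assert np.array_equal(neg_in_organ, raw_neg)
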