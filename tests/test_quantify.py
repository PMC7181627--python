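"""EH ratio and agreement statistics against hand-computed oracles."""

import numpy as np
import pytest

import hydroseg as hs
from hydroseg.quantify import (
    DegenerateDataError,
    EmptyMaskError,
    agreement_report,
    bland_altman,
    eh_ratio,
    eh_report,
    icc_single_two_way,
)


class TestEHRatio:
    def test_all_negative_gives_one(self):
        img = -np.ones((5, 5))
        mask = np.ones((5, 5), bool)
        r = eh_ratio(img, mask)
        assert r.ratio == 1.0 and r.negative_pixels == r.total_pixels == 25

    def test_none_negative_gives_zero(self):
        r = eh_ratio(np.zeros((5, 5)), np.ones((5, 5), bool))
        assert r.ratio == 0.0  # zero-valued pixels are non-endolymph

    def test_empty_mask_is_an_error_not_zero(self):
        with pytest.raises(EmptyMaskError):
            eh_ratio(np.zeros((3, 3)), np.zeros((3, 3), bool))

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((10, 10))
        mask = rng.random((10, 10)) > 0.3
        base = eh_ratio(img, mask).ratio
        for s in (0.01, 3.7, 1e6):
            assert eh_ratio(img * s, mask).ratio == base

    def test_union_ratio_between_component_ratios(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((12, 12))
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[:6] = True
        b[6:] = True  # disjoint
        ra, rb = eh_ratio(img, a).ratio, eh_ratio(img, b).ratio
        ru = eh_ratio(img, a | b).ratio
        assert min(ra, rb) <= ru <= max(ra, rb)

    def test_noiseless_phantom_recovers_requested_fraction(self, small_subject):
        rep = eh_report(small_subject)
        for _, row in rep.iterrows():
            assert abs(row.gt_ratio - 0.35) <= 1.0 / row.gt_total_pixels
            assert row.gt_ratio == row.true_fraction  # exact vs recorded truth


def _icc2_oracle(x, y):
    """From-scratch two-way ANOVA mean squares, ICC(2,1) absolute agreement."""
    n, k = len(x), 2
    data = np.stack([x, y], axis=1)
    gm = data.mean()
    ssr = k * ((data.mean(1) - gm) ** 2).sum()
    ssc = n * ((data.mean(0) - gm) ** 2).sum()
    sse = ((data - gm) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        a = np.random.default_rng(0).random(10)
        icc, ci = icc_single_two_way(a, a)
        assert icc == pytest.approx(1.0)

    def test_hand_computable_four_pair_set(self):
        a = np.array([0.1, 0.3, 0.5, 0.9])
        b = np.array([0.2, 0.3, 0.4, 0.8])
        icc, _ = icc_single_two_way(a, b)
        assert icc == pytest.approx(_icc2_oracle(a, b), abs=1e-10)

    def test_null_pairs_have_icc_near_zero(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(1000), rng.random(1000)
        icc, _ = icc_single_two_way(a, b)
        assert abs(icc) < 3 / np.sqrt(1000)  # ~3 SE under independence

    def test_consistency_variant_differs_under_offset(self):
        rng = np.random.default_rng(3)
        a = rng.random(30)
        b = a + 0.3  # constant offset: consistency 1, absolute < 1
        assert icc_single_two_way(a, b, kind="consistency")[0] == pytest.approx(1.0)
        assert icc_single_two_way(a, b, kind="absolute")[0] < 0.9

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_single_two_way(np.ones(5), np.ones(5))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_single_two_way([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_pairs(self):
        a = np.array([0.2, 0.4, 0.6])
        ba = bland_altman(a, a)
        assert ba.mean_diff == ba.loa_lower == ba.loa_upper == 0.0

    def test_constant_offset(self):
        a = np.array([0.2, 0.4, 0.6])
        ba = bland_altman(a + 0.1, a)
        assert ba.mean_diff == pytest.approx(0.1)
        assert ba.loa_lower == pytest.approx(0.1)
        assert ba.loa_upper == pytest.approx(0.1)

    def test_limits_match_closed_form(self):
        rng = np.random.default_rng(9)
        a, b = rng.random(50), rng.random(50)
        ba = bland_altman(a, b)
        d = a - b
        assert ba.mean_diff == pytest.approx(d.mean())
        assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_lower <= ba.mean_diff <= ba.loa_upper


class TestAgreementReport:
    def test_perfect_agreement_everywhere(self):
        rng = np.random.default_rng(1)
        gt = rng.random(12)
        types = np.array(["cochlea", "vestibule"] * 6)
        rep = agreement_report(gt, gt, types)
        for block in ("overall", "cochlea", "vestibule"):
            assert rep[block].icc == pytest.approx(1.0)
            assert not rep[block].insufficient

    def test_noisier_cochlea_scores_lower_icc(self):
        """Adding more rater noise to cochlea pairs lowers their ICC below
        the vestibule block's, mirroring organ-wise agreement gaps."""
        rng = np.random.default_rng(2)
        n = 40
        truth = rng.uniform(0.1, 0.6, 2 * n)
        types = np.array(["cochlea"] * n + ["vestibule"] * n)
        noise = np.where(types == "cochlea", 0.08, 0.01)
        pred = truth + rng.normal(0, 1, 2 * n) * noise
        rep = agreement_report(truth, pred, types)
        assert rep["vestibule"].icc > rep["cochlea"].icc

    def test_shuffled_pairing_destroys_agreement(self):
        rng = np.random.default_rng(4)
        gt = rng.uniform(0, 1, 200)
        pred = gt + rng.normal(0, 0.02, 200)
        types = np.array(["cochlea", "vestibule"] * 100)
        good = agreement_report(gt, pred, types)["overall"].icc
        shuffled = agreement_report(gt, rng.permutation(pred), types)["overall"].icc
        assert good > 0.95
        assert abs(shuffled) < 0.25

    def test_small_group_flagged_insufficient(self):
        gt = np.array([0.1, 0.2, 0.3, 0.4])
        types = np.array(["cochlea", "cochlea", "cochlea", "vestibule"])
        rep = agreement_report(gt, gt + 0.01, types)
        assert rep["vestibule"].insufficient
        assert not rep["cochlea"].insufficient
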