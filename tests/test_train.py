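"""Folds, IoU, dataset modes, and the training/curriculum machinery."""

import dataclasses

import numpy as np
import pytest

import hydroseg as hs
from hydroseg.segnet import SegModelConfig, build_model
from hydroseg.stack import BACKGROUND, LC, LV, RC, RV
from hydroseg.train import (
    Sample,
    TrainConfig,
    build_patch_dataset,
    curriculum_train,
    evaluate,
    fit,
    iou_binary,
    make_folds,
    mean_iou,
)


class TestFolds:
    def test_ten_ids_make_five_pairs(self):
        folds = make_folds([f"p{i}" for i in range(10)], k=5, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert (sizes == 2).all()

    def test_partition_properties(self):
        ids = [f"p{i}" for i in range(23)]
        folds = make_folds(ids, k=5, seed=1)
        assert set(folds) == set(ids)  # union = all ids, each exactly once
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_372_ids_split_75_75_74_74_74(self):
        folds = make_folds([f"p{i}" for i in range(372)], k=5, seed=2)
        sizes = sorted(np.bincount(list(folds.values()), minlength=5), reverse=True)
        assert sizes == [75, 75, 74, 74, 74]

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(17)]
        assert make_folds(ids, 5, seed=3) == make_folds(ids, 5, seed=3)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5)


class TestIoU:
    def test_identical_masks_score_one(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert iou_binary(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert iou_binary(a, b) == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((8, 8)) > 0.6
            b = rng.random((8, 8)) > 0.6
            v = iou_binary(a, b)
            assert v == iou_binary(b, a)
            assert 0.0 <= v <= 1.0

    def test_mean_iou_class_subset(self):
        gt = np.zeros((6, 6), np.uint8)
        gt[:2, :2] = LC
        gt[4:, 4:] = LV
        pred = gt.copy()
        pred[4:, 4:] = BACKGROUND  # LV missed entirely
        assert mean_iou(pred, gt, classes=(LC,)) == 1.0
        assert mean_iou(pred, gt, classes=(LV,)) == 0.0
        assert mean_iou(pred, gt) == pytest.approx(0.5)

    def test_class_absent_from_gt_is_excluded(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[:2] = LC
        pred = gt.copy()
        pred[3, 3] = RV  # spurious prediction of an absent class
        assert mean_iou(pred, gt) == 1.0
        assert np.isnan(mean_iou(pred, np.zeros((4, 4), np.uint8)))


class TestDatasetModes:
    def test_sa_masks_carry_only_organ_of_interest(self, tiny_cohort, small_spec):
        subjects, manifest = tiny_cohort
        samples = build_patch_dataset(subjects, manifest, small_spec.crop, mode="SA")
        assert samples, "SA pool should not be empty"
        for s in samples:
            labels = set(np.unique(s.y)) - {BACKGROUND}
            assert labels <= set(s.classes_of_interest)
            assert s.pool == "SA"

    def test_fa_masks_carry_visible_organs(self, tiny_cohort, small_spec):
        subjects, manifest = tiny_cohort
        samples = build_patch_dataset(subjects, manifest, small_spec.crop, mode="FA")
        for s in samples:
            assert s.pool == "FA"
            side_rows = manifest[
                (manifest.subject_id == s.subject_id) & (manifest.side == s.side)
            ]
            visible = set(side_rows.loc[side_rows.visible, "label"])
            labels = set(np.unique(s.y)) - {BACKGROUND}
            assert labels <= visible

    def test_fasa_is_union_of_pools(self, tiny_cohort, small_spec):
        subjects, manifest = tiny_cohort
        crop = small_spec.crop
        sa = build_patch_dataset(subjects, manifest, crop, mode="SA")
        fa = build_patch_dataset(subjects, manifest, crop, mode="FA")
        fasa = build_patch_dataset(subjects, manifest, crop, mode="FASA")
        assert {s.sample_id for s in fasa} == {s.sample_id for s in sa} | {
            s.sample_id for s in fa
        }

    def test_fa_prime_restricts_to_organ_of_interest(self, tiny_cohort, small_spec):
        subjects, manifest = tiny_cohort
        samples = build_patch_dataset(subjects, manifest, small_spec.crop, mode="FA'")
        for s in samples:
            assert s.pool == "FA"
            assert set(np.unique(s.y)) - {BACKGROUND} <= set(s.classes_of_interest)

    def test_augmented_dataset_multiplicity(self, tiny_cohort, small_spec):
        subjects, manifest = tiny_cohort
        pol = hs.AugmentationPolicy(shift_range=2, shift_samples_per_direction=1,
                                    flip_states=(False,))
        base = build_patch_dataset(subjects[:1], manifest, small_spec.crop, mode="FASA")
        aug = build_patch_dataset(
            subjects[:1], manifest, small_spec.crop, mode="FASA",
            augmentation="low", policy=pol,
        )
        assert len(aug) == 9 * len(base)
        assert len({s.origin_id for s in aug}) == len(base)


def _stub_samples(n=4):
    rng = np.random.default_rng(0)
    samples = []
    for i in range(n):
        y = np.zeros((8, 8), np.uint8)
        y[2:5, 2:5] = LC
        samples.append(
            Sample(
                x=rng.random((3, 8, 8)),
                y=y,
                sample_id=f"s{i}",
                origin_id=f"s{i}",
                subject_id="sub",
                side="left",
                pool="SA",
                classes_of_interest=(LC,),
            )
        )
    return samples


class _OracleModel:
    """Stub that predicts the ground truth perfectly (one-hot scores)."""

    def __init__(self, samples):
        self._truth = {s.x.tobytes(): s.y for s in samples}

    def forward(self, x, train=False, rng=None):
        N = x.shape[0]
        scores = np.zeros((N, 5) + x.shape[2:])
        for i in range(N):
            y = self._truth[x[i].tobytes()]
            for c in range(5):
                scores[i, c][y == c] = 10.0
        return scores


class _BackgroundModel:
    def forward(self, x, train=False, rng=None):
        scores = np.zeros((x.shape[0], 5) + x.shape[2:])
        scores[:, 0] = 10.0
        return scores


def test_perfect_oracle_model_scores_iou_one():
    samples = _stub_samples()
    assert evaluate(_OracleModel(samples), samples) == 1.0


def test_background_only_model_scores_zero_for_organs():
    samples = _stub_samples()
    assert evaluate(_BackgroundModel(), samples) == 0.0


def _mini_training_setup(tiny_cohort, small_spec, mode="FASA"):
    subjects, manifest = tiny_cohort
    samples = build_patch_dataset(subjects, manifest, small_spec.crop, mode=mode)
    folds = make_folds(sorted({s.origin_id for s in samples}), k=3, seed=0)
    tr = [s for s in samples if folds[s.origin_id] != 0]
    va = [s for s in samples if folds[s.origin_id] == 0]
    return tr, va


def test_fit_is_deterministic(tiny_cohort, small_spec):
    tr, va = _mini_training_setup(tiny_cohort, small_spec)
    cfg = SegModelConfig(encoder_depth=8, channel_scale=0.0625, dropout=0.1)
    tcfg = TrainConfig(learning_rate=1e-3, dropout=0.1, epochs=1, seed=5)
    r1 = fit(build_model(cfg, seed=5), tr, va, tcfg)
    r2 = fit(build_model(cfg, seed=5), tr, va, tcfg)
    for k in r1.final_state:
        assert np.array_equal(r1.final_state[k], r2.final_state[k])
    assert r1.epoch_val_iou == r2.epoch_val_iou


def test_zero_epochs_leaves_weights_untouched(tiny_cohort, small_spec):
    tr, va = _mini_training_setup(tiny_cohort, small_spec)
    cfg = SegModelConfig(encoder_depth=8, channel_scale=0.0625, dropout=0.1)
    model = build_model(cfg, seed=1)
    before = model.state_dict()
    res = fit(model, tr, va, TrainConfig(learning_rate=1e-3, epochs=0, seed=0))
    for k in before:
        assert np.array_equal(before[k], res.final_state[k])


def test_curriculum_resumes_stage1_weights(tiny_cohort, small_spec):
    """Stage 2 with 0 epochs returns exactly the stage-1 final weights."""
    subjects, manifest = tiny_cohort
    crop = small_spec.crop
    sa = build_patch_dataset(subjects, manifest, crop, mode="SA")
    fasa = build_patch_dataset(subjects, manifest, crop, mode="FASA")
    cfg = SegModelConfig(encoder_depth=8, channel_scale=0.0625)
    model, res1, res2 = curriculum_train(
        sa, fasa, fasa[:4], cfg,
        TrainConfig(learning_rate=1e-3, dropout=0.1, epochs=1, seed=2),
        TrainConfig(learning_rate=1e-3, dropout=0.1, epochs=0, seed=3),
    )
    final = model.state_dict()
    for k in final:
        assert np.array_equal(final[k], res1.final_state[k])
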