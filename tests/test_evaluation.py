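"""Metrics (dice, AUC), dataset-construction rules, protocol mechanics."""

import numpy as np
import pytest

from mammogan.evaluation import (LabeledPatch, ProtocolConfig, SegExample,
                                 build_calc_patch_dataset, dice_score,
                                 grouped_folds, roc_auc, run_protocol,
                                 seg_examples_from_images, summarize_protocol)
from mammogan.image import BreastMask, GrayscaleImage


def _brute_force_auc(labels, scores):
    """All positive-negative pairs: wins + half-ties."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += (p > n) + 0.5 * (p == n)
    return total / (len(pos) * len(neg))


class TestDice:
    def test_identical_masks(self, rng):
        m = (rng.uniform(size=(16, 16)) > 0.5).astype(int)
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), int)
        b = np.zeros((4, 4), int)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_score(a, b) == 0.0

    def test_printed_example_six_four_three(self):
        a = np.zeros(16, int)
        b = np.zeros(16, int)
        a[:6] = 1
        b[3:7] = 1          # |A|=6, |B|=4, |A∩B|=3
        assert dice_score(a.reshape(4, 4), b.reshape(4, 4)) == pytest.approx(0.6)

    def test_symmetric_and_empty_defined_as_one(self, rng):
        a = (rng.uniform(size=(8, 8)) > 0.5).astype(int)
        b = (rng.uniform(size=(8, 8)) > 0.5).astype(int)
        assert dice_score(a, b) == pytest.approx(dice_score(b, a))
        assert dice_score(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((4, 4)), np.zeros((4, 5)))


class TestRocAuc:
    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = np.round(rng.normal(size=n), 1)   # induce ties
            assert roc_auc(labels, scores) == pytest.approx(
                _brute_force_auc(labels, scores), abs=1e-12)

    def test_printed_four_point_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation_and_pure_ties(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_antisymmetry_under_score_negation(self, rng):
        labels = np.array([0, 1] * 10)
        scores = rng.normal(size=20)
        assert (roc_auc(labels, scores) + roc_auc(labels, -scores)
                == pytest.approx(1.0))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=50)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestCalcPatchDataset:
    def _img_mask(self):
        px = np.zeros((64, 64))
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[:, :40] = 1                 # left 40 columns are breast
        px[:, :40] = 0.5
        return GrayscaleImage(px, 0.1), BreastMask(mask, 0.1)

    def test_background_tiles_removed_at_eighty_percent_rule(self):
        img, mask = self._img_mask()
        tiles = build_calc_patch_dataset(img, mask, [], side=32)
        # right column of tiles is 75% background (<= 0.80): kept;
        # construct a case above the threshold to see removal
        assert {t.origin_rc for t in tiles} == {(0, 0), (0, 32), (32, 0), (32, 32)}
        mask85 = np.zeros((64, 64), dtype=np.uint8)
        mask85[:, :36] = 1               # right tiles: 28/32 = 87.5% bg
        tiles = build_calc_patch_dataset(img, BreastMask(mask85, 0.1), [],
                                         side=32)
        assert {t.origin_rc for t in tiles} == {(0, 0), (32, 0)}

    def test_labels_follow_calcification_presence(self):
        img, mask = self._img_mask()
        tiles = build_calc_patch_dataset(img, mask, [(5, 5), (40, 10)], side=32)
        by_origin = {t.origin_rc: t.label for t in tiles}
        assert by_origin[(0, 0)] == 1     # one calc inside
        assert by_origin[(32, 0)] == 1    # the other
        assert by_origin[(0, 32)] == 0 and by_origin[(32, 32)] == 0

    def test_two_calcs_in_one_tile_still_label_one(self):
        img, mask = self._img_mask()
        tiles = build_calc_patch_dataset(img, mask, [(5, 5), (6, 6)], side=32)
        assert {t.origin_rc: t.label for t in tiles}[(0, 0)] == 1


class TestFoldsAndProtocol:
    def test_grouped_folds_partition_exactly_once(self, rng):
        groups = np.repeat(np.arange(10), 3)
        folds = grouped_folds(groups, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(30))
        for f in folds:                   # groups never straddle folds
            for g in np.unique(groups[f]):
                assert set(np.flatnonzero(groups == g)) <= set(f)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            grouped_folds([0, 0, 1, 1], 5)

    def _tiny_seg_data(self, rng, n=10):
        out = []
        for g in range(n):
            px = rng.uniform(-1, 1, size=(8, 16))
            tgt = np.zeros((8, 16), dtype=np.uint8)
            tgt[2:5, 3:7] = 1
            out.append(SegExample(px, tgt, g))
        return out

    def test_empty_pretrain_collapses_to_baseline(self, rng):
        data = self._tiny_seg_data(rng)
        cfg = ProtocolConfig(train_steps=5, pretrain_steps=5, seed=1)
        res = run_protocol("mass_segmentation", data, None, 5, cfg)
        wide = res.pivot_table(index="fold", columns="arm", values="value")
        np.testing.assert_array_equal(wide["baseline"], wide["finetuned"])

    def test_five_folds_two_arms_reported(self, rng):
        data = self._tiny_seg_data(rng)
        cfg = ProtocolConfig(train_steps=3, pretrain_steps=3, seed=1)
        pre = self._tiny_seg_data(rng, 4)
        res = run_protocol("mass_segmentation", data, pre, 5, cfg)
        assert len(res) == 10
        assert set(res.arm) == {"baseline", "finetuned"}
        summary = summarize_protocol(res)
        assert summary.loc[0, "n_folds"] == 5

    def test_detection_protocol_runs(self, rng):
        data = [LabeledPatch(rng.uniform(-1, 1, size=(16, 16)),
                             int(rng.integers(2)), (0, 0), g)
                for g in range(10)]
        cfg = ProtocolConfig(train_steps=3, pretrain_steps=3, seed=0)
        res = run_protocol("calc_detection", data, data[:4], 5, cfg)
        assert res.metric.eq("auc").all()

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            run_protocol("density_estimation", [], None, 5)


def test_seg_examples_downsample_and_normalize(rng):
    imgs = [rng.uniform(0, 100, size=(16, 32))]
    masks = [np.pad(np.ones((8, 16)), ((0, 8), (0, 16)))]
    ex = seg_examples_from_images(imgs, masks, [7], downsample=4)[0]
    assert ex.pixels.shape == (4, 8) and ex.target.shape == (4, 8)
    assert ex.pixels.min() >= -1 and ex.pixels.max() <= 1
    assert ex.group == 7
    np.testing.assert_array_equal(ex.target[:2, :4], 1)
    np.testing.assert_array_equal(ex.target[2:, 4:], 0)
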