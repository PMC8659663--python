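"""Losses, augmentation protocols, training loop and segmentation metrics."""

import math

import numpy as np
import pytest

from sicklenet import segmentation as seg
from sicklenet.nn import SegNet

from oracles import (
    binomial_99_interval,
    cross_entropy_brute,
    jaccard_index_brute,
    jaccard_loss_brute,
)


def _random_instance(rng, n_pixels):
    """Random one-hot truth and softmax prediction with <= 10 pixels."""
    p = np.eye(3)[rng.integers(0, 3, n_pixels)]
    q = rng.dirichlet(np.ones(3), size=n_pixels)
    return p, q


class TestLosses:
    @pytest.mark.parametrize("n_pixels", [1, 2, 5, 10])
    def test_losses_match_bruteforce_oracles(self, n_pixels, rng):
        """Vectorized CE and Jaccard losses agree with explicit-loop
        implementations to 1e-9 on small instances."""
        for _ in range(5):
            p, q = _random_instance(rng, n_pixels)
            assert abs(seg.cross_entropy_loss(p, q)
                       - cross_entropy_brute(p, q)) < 1e-9
            assert abs(seg.jaccard_loss(p, q)
                       - jaccard_loss_brute(p, q)) < 1e-9
            breakdown = seg.combined_loss(p, q)
            assert abs(breakdown.total
                       - (breakdown.l_ce + breakdown.l_jac)) < 1e-12

    def test_cross_entropy_hand_example(self):
        """N=1, p=(1,0,0), q=(0.5,0.25,0.25):
        L_CE = -[ln 0.5 + ln 0.75 + ln 0.75]."""
        p = np.array([[1.0, 0.0, 0.0]])
        q = np.array([[0.5, 0.25, 0.25]])
        expected = -(math.log(0.5) + math.log(0.75) + math.log(0.75))
        assert abs(seg.cross_entropy_loss(p, q) - expected) < 1e-12

    def test_jaccard_hand_example_gives_ln3(self):
        """Two pixels with sum(pq)=1 give J = 1/3 and loss ln 3."""
        p = np.array([[1, 0, 0], [0, 1, 0]], dtype=float)
        q = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]])
        assert abs(seg.jaccard_loss(p, q) - math.log(3)) < 1e-9
        total = seg.combined_loss(p, q)
        assert abs(total.total
                   - (seg.cross_entropy_loss(p, q) + math.log(3))) < 1e-9

    def test_perfect_prediction_losses_vanish(self):
        p = np.eye(3)[np.array([0, 1, 2, 1])]
        assert seg.cross_entropy_loss(p, p) < 1e-5
        assert seg.jaccard_loss(p, p) < 1e-5

    def test_duplicating_batch_leaves_ce_unchanged(self, rng):
        p, q = _random_instance(rng, 6)
        doubled = (np.concatenate([p, p]), np.concatenate([q, q]))
        assert abs(seg.cross_entropy_loss(p, q)
                   - seg.cross_entropy_loss(*doubled)) < 1e-12
        assert abs(seg.jaccard_loss(p, q)
                   - seg.jaccard_loss(*doubled)) < 1e-12

    def test_disjoint_prediction_hits_clamp_ceiling(self):
        p = np.eye(3)[np.zeros(4, dtype=int)]
        q = np.eye(3)[np.ones(4, dtype=int)]
        assert seg.jaccard_loss(p, q) > 10.0

    def test_total_not_below_components(self, rng):
        p, q = _random_instance(rng, 8)
        b = seg.combined_loss(p, q)
        assert b.total >= b.l_ce - 1e-12
        assert b.total >= b.l_jac - 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.cross_entropy_loss(np.eye(3), np.eye(3)[:2])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            seg.jaccard_loss(np.zeros((0, 3)), np.zeros((0, 3)))


class TestBalanceAugment:
    @staticmethod
    def _tiles(n_adhered, n_other, n_background, size=8):
        tiles = []
        for kind, count in (("a", n_adhered), ("o", n_other),
                            ("b", n_background)):
            for _ in range(count):
                mask = np.zeros((size, size), dtype=np.uint8)
                if kind == "a":
                    mask[2, 2] = 1
                elif kind == "o":
                    mask[3, 3] = 2
                tiles.append((np.zeros((size, size), dtype=np.float32), mask))
        return tiles

    def test_published_corpus_arithmetic(self):
        """877 adhered and 360 other tiles from a 3,500-tile corpus expand
        by 2,631 + 1,080 rotated samples to 7,211 total."""
        tiles = self._tiles(877, 360, 3500 - 877 - 360)
        out, report = seg.balance_augment(tiles)
        assert report.n_new_adhered == 2631
        assert report.n_new_other == 1080
        assert report.n_total == len(out) == 7211

    def test_no_selected_tiles_adds_nothing(self):
        tiles = self._tiles(0, 0, 5)
        out, report = seg.balance_augment(tiles)
        assert len(out) == 5
        assert report.n_new_adhered == report.n_new_other == 0

    def test_rotation_inverse_recovers_original(self, rng):
        image = rng.random((8, 8)).astype(np.float32)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[1, 5] = 1
        out, report = seg.balance_augment([(image, mask)])
        assert report.n_new_adhered == 3
        for k, (img_rot, msk_rot) in enumerate(out[1:], start=1):
            np.testing.assert_array_equal(np.rot90(img_rot, 4 - k), image)
            np.testing.assert_array_equal(np.rot90(msk_rot, 4 - k), mask)

    def test_minority_fraction_strictly_increases(self):
        tiles = self._tiles(2, 1, 17)
        out, _ = seg.balance_augment(tiles)
        before = np.mean([(m > 0).any() for _, m in tiles])
        after = np.mean([(m > 0).any() for _, m in out])
        assert after > before

    def test_non_square_tile_rejected(self):
        with pytest.raises(ValueError, match="square"):
            seg.balance_augment([(np.zeros((4, 6)), np.ones((4, 6), np.uint8))])


class TestRandomAugment:
    def test_deterministic_under_fixed_generator_state(self, rng):
        image = rng.random((32, 32)).astype(np.float32)
        mask = (rng.random((32, 32)) > 0.8).astype(np.uint8)
        a = seg.random_augment(image, mask, rng=np.random.default_rng(5))
        b = seg.random_augment(image, mask, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_identity_params_change_nothing(self, rng):
        image = rng.random((16, 16)).astype(np.float32)
        out = seg.random_augment(image, params=(False, False, 0.0))
        np.testing.assert_allclose(out, image, atol=1e-6)

    def test_flip_frequency_within_binomial_interval(self):
        """Horizontal flips occur with p=0.5: over 10,000 draws the
        frequency stays inside the 99% binomial interval."""
        gen = np.random.default_rng(99)
        draws = [seg.draw_augment_params(gen) for _ in range(10_000)]
        freq_h = np.mean([d[0] for d in draws])
        freq_v = np.mean([d[1] for d in draws])
        angles = np.array([d[2] for d in draws])
        half = binomial_99_interval(0.5, 10_000)
        assert abs(freq_h - 0.5) <= half
        assert abs(freq_v - 0.5) <= half
        assert angles.min() >= -90.0 and angles.max() <= 90.0

    def test_mask_stays_integer_labelled(self, rng):
        image = rng.random((24, 24)).astype(np.float32)
        mask = rng.integers(0, 3, (24, 24)).astype(np.uint8)
        _, out_mask = seg.random_augment(image, mask,
                                         rng=np.random.default_rng(2))
        assert set(np.unique(out_mask)) <= {0, 1, 2}


class TestTraining:
    def test_zero_epochs_leaves_weights_at_initialization(self, rng):
        x = rng.random((10, 16, 16, 3)).astype(np.float32)
        y = rng.integers(0, 3, (10, 16, 16))
        config = seg.SegModelConfig(depth=1, base_filters=2, epochs=0, seed=3)
        models, histories, _ = seg.train_segmenter(x, y, config)
        fresh = SegNet(depth=1, base_filters=2, seed=3)
        for a, b in zip(models[0].params, fresh.params):
            np.testing.assert_array_equal(a.data, b.data)
        assert len(histories[0]) == 0

    def test_overfitting_a_tiny_batch_reduces_loss(self, seg_corpus):
        """A few dozen gradient steps on 8 tiles at a fixed seed lower the
        training loss below its initial value."""
        _, x, y = seg_corpus
        config = seg.SegModelConfig(depth=2, base_filters=4, epochs=4,
                                    batch_size=4, augment=False, seed=1)
        _, histories, _ = seg.train_segmenter(x[:8], y[:8], config)
        h = histories[0]
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_kfold_training_returns_disjoint_covering_folds(self, rng):
        x = rng.random((20, 8, 8, 3)).astype(np.float32)
        y = rng.integers(0, 3, (20, 8, 8))
        config = seg.SegModelConfig(depth=1, base_filters=2, epochs=1,
                                    batch_size=8, augment=False, seed=0)
        models, histories, splits = seg.train_segmenter(x, y, config, folds=5)
        assert len(models) == len(histories) == 5
        all_val = np.concatenate([v for _, v in splits])
        assert len(all_val) == 20
        assert len(np.unique(all_val)) == 20

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seg.train_segmenter(np.zeros((0, 8, 8, 3)), np.zeros((0, 8, 8)),
                                seg.SegModelConfig())


class TestEnsemble:
    def test_identical_members_equal_single_model(self, rng):
        net = SegNet(depth=1, base_filters=2, seed=4)
        x = rng.random((2, 8, 8, 3)).astype(np.float32)
        single = seg.segment_tiles(net, x)
        triple = seg.segment_tiles([net, net, net], x)
        np.testing.assert_allclose(single, triple, atol=1e-7)

    def test_two_member_average_is_arithmetic_mean(self, rng):
        a = SegNet(depth=1, base_filters=2, seed=5)
        b = SegNet(depth=1, base_filters=2, seed=6)
        x = rng.random((1, 8, 8, 3)).astype(np.float32)
        qa = seg.segment_tiles(a, x)
        qb = seg.segment_tiles(b, x)
        qab = seg.segment_tiles([a, b], x)
        np.testing.assert_allclose(qab, (qa + qb) / 2, atol=1e-6)
        np.testing.assert_allclose(qab.sum(axis=-1), 1.0, atol=1e-5)


class TestSegMetrics:
    def test_perfect_prediction_scores_unity(self, rng):
        y = rng.integers(0, 3, (12, 12))
        m = seg.seg_metrics(y, y)
        assert (m.pixel_accuracy, m.jaccard, m.dice) == (1.0, 1.0, 1.0)

    def test_dice_follows_from_jaccard_identity(self, rng):
        """D = 2J/(1+J) on every evaluated pair, with D >= J."""
        for _ in range(10):
            pred = rng.integers(0, 3, (9, 9))
            truth = rng.integers(0, 3, (9, 9))
            m = seg.seg_metrics(pred, truth)
            assert abs(m.dice - 2 * m.jaccard / (1 + m.jaccard)) < 1e-12
            assert m.dice >= m.jaccard

    def test_jaccard_matches_bruteforce_index_on_label_grids(self, rng):
        pred = rng.integers(0, 3, (3, 3))
        truth = rng.integers(0, 3, (3, 3))
        m = seg.seg_metrics(pred, truth)
        p = np.eye(3)[truth]
        q = np.eye(3)[pred]
        assert abs(m.jaccard - jaccard_index_brute(p, q, eps=0.0)) < 1e-9

    def test_completely_wrong_masks_score_zero_accuracy(self):
        pred = np.ones((6, 6), dtype=int)
        truth = np.full((6, 6), 2)
        m = seg.seg_metrics(pred, truth)
        assert m.pixel_accuracy == 0.0

    def test_per_class_iou_hand_instance(self):
        pred = np.array([[1, 1, 0], [0, 0, 0]])
        truth = np.array([[1, 0, 0], [1, 0, 0]])
        # intersection 1, union 3
        assert seg.per_class_iou(pred, truth, 1) == pytest.approx(1 / 3)
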