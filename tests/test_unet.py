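"""Training machinery: folds, augmentation, descent, transfer learning."""

import numpy as np
import pytest

from adenovol import (
    AugmentConfig,
    TrainConfig,
    TrainedModel,
    augment_slice,
    dice,
    make_folds,
    train_fold,
    transfer_init,
)
from adenovol.nn import UNet2D, bce_with_logits


def blob_slices(n=8, size=16, seed=0):
    """Easy training data: bright squares on noisy background."""
    rng = np.random.default_rng(seed)
    imgs = rng.normal(0, 0.3, size=(n, size, size))
    masks = np.zeros((n, size, size))
    for i in range(n):
        r, c = rng.integers(2, size - 6, size=2)
        h, w = rng.integers(3, 6, size=2)
        masks[i, r : r + h, c : c + w] = 1
    imgs += 3.0 * masks
    return imgs, masks


class TestMakeFolds:
    def test_balanced_partition(self):
        ids = [f"P{i}" for i in range(20)]
        split = make_folds(ids, 5, seed=1)
        sizes = [len(split.val_ids(j)) for j in range(5)]
        assert sizes == [4] * 5

    def test_exhaustive_and_disjoint(self):
        ids = [f"P{i}" for i in range(13)]
        split = make_folds(ids, 4, seed=2)
        folds = [set(split.val_ids(j)) for j in range(4)]
        assert set().union(*folds) == set(ids)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not folds[i] & folds[j]
        assert max(map(len, folds)) - min(map(len, folds)) <= 1

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"P{i}" for i in range(20)]
        assert make_folds(ids, 5, seed=7) == make_folds(ids, 5, seed=7)
        assert make_folds(ids, 5, seed=7) != make_folds(ids, 5, seed=8)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_folds(["A", "A", "B"], 2, seed=0)

    def test_train_val_complement(self):
        ids = [f"P{i}" for i in range(10)]
        split = make_folds(ids, 5, seed=3)
        for j in range(5):
            assert sorted(split.train_ids(j) + split.val_ids(j)) == sorted(ids)


class TestAugmentSlice:
    def test_identity_at_zero_rotation_and_zoom(self, rng):
        cfg = AugmentConfig(rotation_deg=(0, 0), zoom=(0, 0))
        img = rng.normal(size=(16, 16))
        mask = (rng.uniform(size=(16, 16)) > 0.8).astype(np.uint8)
        out_img, out_mask = augment_slice(img, mask, cfg, rng)
        assert np.allclose(out_img, img, atol=1e-9)
        assert np.array_equal(out_mask, mask)

    def test_mask_stays_binary(self, rng):
        cfg = AugmentConfig()
        img = rng.normal(size=(16, 16))
        mask = (rng.uniform(size=(16, 16)) > 0.7).astype(np.uint8)
        for _ in range(20):
            _, out_mask = augment_slice(img, mask, cfg, rng)
            assert set(np.unique(out_mask)) <= {0, 1}

    def test_draw_ranges_exhaustive(self):
        # 1000 seeded draws all fall in angle [0, 90] deg, zoom [1.0, 1.3]
        cfg = AugmentConfig()
        rng = np.random.default_rng(5)
        angles = rng.uniform(*cfg.rotation_deg, size=1000)
        zooms = 1.0 + rng.uniform(*cfg.zoom, size=1000)
        assert angles.min() >= 0 and angles.max() <= 90
        assert zooms.min() >= 1.0 and zooms.max() <= 1.3

    def test_zoom_magnifies_mask(self, rng):
        cfg = AugmentConfig(rotation_deg=(0, 0), zoom=(0.3, 0.3))
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[6:10, 6:10] = 1
        _, out_mask = augment_slice(np.zeros((16, 16)), mask, cfg, rng)
        assert out_mask.sum() > mask.sum()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            augment_slice(np.zeros((8, 8)), np.zeros((8, 9)), AugmentConfig(), rng)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rotation_deg=(0, 120))
        with pytest.raises(ValueError):
            AugmentConfig(zoom=(0, 0.5))
        with pytest.raises(ValueError):
            AugmentConfig(sampling_ratio=0.0)


class TestTrainFold:
    CFG = TrainConfig(folds=5, epochs=80, batch_size=4, learning_rate=3e-3,
                      base_filters=4, depth=2, seed=0)

    def test_overfits_single_batch(self):
        imgs, masks = blob_slices(n=4)
        model = train_fold(imgs, masks, self.CFG)
        pred = (model.predict(imgs) >= 0.5).astype(np.uint8)
        scores = [dice(pred[i][None], masks[i][None].astype(np.uint8)) for i in range(4)]
        assert min(scores) > 0.9

    def test_loss_descends(self):
        imgs, masks = blob_slices(n=16, seed=3)
        cfg = TrainConfig(epochs=5, batch_size=4, learning_rate=3e-3,
                          base_filters=4, depth=2, seed=1)
        model = train_fold(imgs, masks, cfg)
        assert model.history[-1] < model.history[0]

    def test_first_epoch_reproducible(self):
        imgs, masks = blob_slices(n=8, seed=4)
        cfg = TrainConfig(epochs=1, batch_size=4, base_filters=4, depth=2, seed=9)
        a = train_fold(imgs, masks, cfg)
        b = train_fold(imgs, masks, cfg)
        assert a.history == b.history
        x = imgs[:2]
        assert np.array_equal(a.predict(x), b.predict(x))

    def test_predictions_in_open_unit_interval(self):
        imgs, masks = blob_slices(n=4)
        cfg = TrainConfig(epochs=1, batch_size=4, base_filters=4, depth=2, seed=0)
        model = train_fold(imgs, masks, cfg)
        p = model.predict(imgs)
        assert p.min() > 0 and p.max() < 1

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_fold(np.zeros((0, 8, 8)), np.zeros((0, 8, 8)), self.CFG)

    def test_save_load_bit_exact(self, tmp_path):
        imgs, masks = blob_slices(n=4)
        cfg = TrainConfig(epochs=2, batch_size=4, base_filters=4, depth=2, seed=0)
        model = train_fold(imgs, masks, cfg, phase="preop", fold=3)
        model.save(tmp_path / "preop_fold3")
        back = TrainedModel.load(tmp_path / "preop_fold3")
        assert back.phase == "preop" and back.fold == 3
        assert np.array_equal(model.predict(imgs), back.predict(imgs))


class TestTransferInit:
    def _model(self, seed=0, depth=2, filters=4):
        imgs, masks = blob_slices(n=4)
        cfg = TrainConfig(epochs=1, batch_size=4, base_filters=filters, depth=depth, seed=seed)
        return train_fold(imgs, masks, cfg)

    def test_clone_predicts_identically_before_training(self):
        donor = self._model()
        clone = transfer_init(donor)
        x = np.random.default_rng(1).normal(size=(3, 16, 16))
        assert np.array_equal(donor.predict(x), clone.predict(x))
        assert clone.phase == "postop"

    def test_donor_isolated_from_recipient_training(self):
        donor = self._model()
        x = np.random.default_rng(1).normal(size=(3, 16, 16))
        before = donor.predict(x)
        imgs, masks = blob_slices(n=8, seed=8)
        cfg = TrainConfig(epochs=2, batch_size=4, base_filters=4, depth=2, seed=5)
        trained = train_fold(imgs, masks, cfg, init_model=transfer_init(donor))
        assert np.array_equal(donor.predict(x), before)
        assert not np.array_equal(trained.predict(x), before)

    def test_architecture_mismatch_rejected(self):
        donor = self._model(depth=2)
        bad = TrainConfig(depth=3, base_filters=4)
        with pytest.raises(ValueError, match="mismatch"):
            transfer_init(donor, bad)


class TestEngine:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = UNet2D(depth=2, base_filters=2, seed=1, dtype=np.float64)
        x = rng.normal(size=(2, 1, 8, 8))
        y = (rng.uniform(size=(2, 1, 8, 8)) > 0.7).astype(float)
        logits = net.forward(x, train=True)
        _, dz = bce_with_logits(logits, y)
        net.backward(dz)
        checks = 0
        for p, g in net.params():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = bce_with_logits(net.forward(x), y)
            p[idx] = orig - eps
            lm, _ = bce_with_logits(net.forward(x), y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-9)
            checks += 1
        assert checks >= 5

    def test_indivisible_input_rejected(self):
        net = UNet2D(depth=3, base_filters=2)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 10, 10)))
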