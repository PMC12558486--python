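"""U-Net mechanics (shapes, gradients, determinism), augmentation
contracts, the learning-rate schedule and the classical baseline."""

import numpy as np
import pytest

from respiro.preprocess import NetworkInput
from respiro.segmentation import (
    AUGMENT_OPS,
    TrainConfig,
    TrainHistory,
    UNetConfig,
    augment_pair,
    build_unet,
    classical_segment,
    dice_loss_and_grad,
    load_checkpoint,
    predict_mask,
    predict_probabilities,
    save_checkpoint,
    train_unet,
)


def _tiny(seed=0, depth=2, base=2):
    return build_unet(UNetConfig(depth_levels=depth, base_filters=base), seed=seed)


def _net_input(img):
    return NetworkInput(image=img, side_px=img.shape[0])


class TestArchitecture:
    def test_full_scale_profile_constructible(self):
        cfg = UNetConfig(depth_levels=5, base_filters=32)
        assert cfg.encoder_channels == [32, 64, 128, 256, 512]
        assert cfg.divisor == 16
        build_unet(cfg)  # must not raise

    def test_forward_shape_and_probability_simplex(self):
        model = _tiny()
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        probs = model.forward(x)
        assert probs.shape == (2, 2, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()

    def test_input_side_must_be_divisible(self):
        model = _tiny(depth=3)  # divisor 4
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 18, 18)))

    def test_same_seed_same_weights(self):
        w1 = _tiny(seed=7).get_weights()
        w2 = _tiny(seed=7).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_untrained_head_predicts_uniform(self):
        """The classification head starts at zero so the softmax opens at
        (0.5, 0.5) instead of saturating."""
        probs = _tiny(seed=1).forward(np.random.default_rng(1).random((1, 1, 16, 16)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic loss gradient w.r.t. a sample of weights matches central
        finite differences (1e-2 relative: conv internals are float32)."""
        rng = np.random.default_rng(3)
        model = _tiny(seed=3)
        x = rng.random((1, 1, 8, 8))
        t = (rng.random((1, 8, 8)) < 0.3).astype(np.int64)

        def loss_of():
            return dice_loss_and_grad(model.forward(x), t)[0]

        model.zero_grad()
        probs = model.forward(x)
        _, dprobs = dice_loss_and_grad(probs, t)
        model.backward(dprobs, probs)

        eps = 1e-4
        checked = 0
        for w, g, _ in model._params():
            flat_w, flat_g = w.reshape(-1), g.reshape(-1)
            for k in rng.choice(flat_w.size, size=min(3, flat_w.size), replace=False):
                orig = flat_w[k]
                flat_w[k] = orig + eps
                lp = loss_of()
                flat_w[k] = orig - eps
                lm = loss_of()
                flat_w[k] = orig
                num = (lp - lm) / (2 * eps)
                # hybrid tolerance: conv internals run in float32, so tiny
                # gradients carry absolute noise around 1e-7
                tol = 1e-7 + 1e-2 * max(abs(num), abs(flat_g[k]))
                assert abs(num - flat_g[k]) <= tol, \
                    f"grad mismatch {num} vs {flat_g[k]}"
                checked += 1
        assert checked > 10

    def test_dice_loss_bounds_and_perfect_prediction(self):
        t = np.zeros((1, 8, 8), dtype=np.int64)
        t[0, :4] = 1
        perfect = np.zeros((1, 2, 8, 8))
        perfect[0, 0] = t[0] == 0
        perfect[0, 1] = t[0] == 1
        loss, _ = dice_loss_and_grad(perfect, t)
        assert loss < 1e-5
        uniform = np.full((1, 2, 8, 8), 0.5)
        lu, _ = dice_loss_and_grad(uniform, t)
        assert 0 < lu < 1


class TestSchedule:
    def test_stepped_halving_every_period(self):
        tc = TrainConfig(learning_rate=0.01, lr_drop_factor=0.5,
                         lr_drop_period_epochs=75)
        assert tc.lr_at(0) == 0.01
        assert tc.lr_at(74) == 0.01
        assert tc.lr_at(75) == 0.005
        assert tc.lr_at(150) == 0.0025

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(lr_drop_factor=0.0)


class TestAugmentation:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64))
        msk = np.zeros((64, 64), dtype=bool)
        msk[20:40, 25:45] = True
        return img, msk

    def test_mask_stays_binary_image_stays_in_range(self):
        img, msk = self._pair()
        for seed in range(10):
            ai, am = augment_pair(img, msk, AUGMENT_OPS, seed=seed)
            assert am.dtype == bool
            assert 0.0 <= ai.min() and ai.max() <= 1.0
            assert ai.shape == img.shape and am.shape == msk.shape

    def test_geometric_ops_move_image_and_mask_together(self):
        img, msk = self._pair()
        ai, am = augment_pair(img, msk, ("rotation", "scale", "shear"), seed=4)
        # mask area roughly preserved under rigid-ish transforms
        assert 0.6 < am.sum() / msk.sum() < 1.6
        # the mask must track the image: masked-region mean stays distinct
        img2 = img.copy()
        img2[msk] += 2.0  # bright object
        ai2, am2 = augment_pair(np.clip(img2 / 3, 0, 1), msk,
                                ("rotation", "scale", "shear"), seed=4)
        assert ai2[am2].mean() > ai2[~am2].mean()

    def test_photometric_ops_do_not_touch_mask(self):
        img, msk = self._pair()
        _, am = augment_pair(img, msk, ("blur", "noise", "brightness", "contrast"),
                             seed=2)
        np.testing.assert_array_equal(am, msk)

    def test_seed_reproducible(self):
        img, msk = self._pair()
        a = augment_pair(img, msk, AUGMENT_OPS, seed=9)
        b = augment_pair(img, msk, AUGMENT_OPS, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_unknown_op_rejected(self):
        img, msk = self._pair()
        with pytest.raises(ValueError, match="unknown"):
            augment_pair(img, msk, ("sharpen",))


class TestTrainingMechanics:
    def _toy_set(self, n=2, side=16, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            msk = np.zeros((side, side), dtype=bool)
            r, c = rng.integers(4, side - 4, 2)
            msk[r - 3 : r + 3, c - 3 : c + 3] = True
            img = 0.3 + 0.5 * msk + rng.normal(0, 0.02, (side, side))
            out.append((np.clip(img, 0, 1), msk))
        return out

    def test_loss_decreases_on_toy_problem(self):
        model = _tiny(seed=0)
        data = self._toy_set()
        tc = TrainConfig(learning_rate=0.03, batch_size=2, epochs=12,
                         augment_fraction=0.0, seed=0)
        hist = train_unet(model, data, None, tc)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_training_deterministic_for_fixed_seed(self):
        tc = TrainConfig(learning_rate=0.03, batch_size=2, epochs=3,
                         augment_fraction=1.0, seed=5)
        runs = []
        for _ in range(2):
            model = _tiny(seed=2)
            train_unet(model, self._toy_set(), None, tc)
            runs.append(model.get_weights())
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_best_validation_weights_restored(self):
        model = _tiny(seed=1)
        data = self._toy_set()
        tc = TrainConfig(learning_rate=0.05, batch_size=2, epochs=8,
                         augment_fraction=0.0, seed=1)
        hist = train_unet(model, data, data, tc)
        assert hist.best_epoch >= 0
        assert hist.final_weights is not None
        # reported validation Dice at best_epoch is the maximum seen
        assert hist.val_dice[hist.best_epoch] == max(hist.val_dice)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_unet(_tiny(), [], None, TrainConfig())


class TestPredictionAndCheckpoint:
    def test_probability_map_range_and_mask_threshold(self):
        model = _tiny(seed=4)
        x = _net_input(np.random.default_rng(4).random((16, 16)))
        p = predict_probabilities(model, x)
        assert p.shape == (16, 16) and (0 <= p).all() and (p <= 1).all()
        m = predict_mask(model, x, threshold=0.5)
        np.testing.assert_array_equal(m.mask, p >= 0.5)

    def test_checkpoint_roundtrip_identical_predictions(self, tmp_path):
        model = _tiny(seed=6, depth=3, base=4)
        x = np.random.default_rng(6).random((1, 1, 16, 16))
        p1 = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, TrainConfig())
        back = load_checkpoint(path)
        np.testing.assert_array_equal(back.forward(x), p1)


class TestClassicalBaseline:
    def test_bimodal_image_thresholded_correctly(self):
        rng = np.random.default_rng(0)
        msk = np.zeros((64, 64), dtype=bool)
        msk[16:48, 16:48] = True
        img = 0.3 + 0.4 * msk + rng.normal(0, 0.02, (64, 64))
        out = classical_segment(_net_input(np.clip(img, 0, 1)))
        inter = (out.mask & msk).sum()
        union = (out.mask | msk).sum()
        # the 1-px Gaussian pre-smoothing blurs the square's border, so a
        # 32-px object loses some boundary IoU by construction
        assert inter / union > 0.85

    def test_constant_image_returns_empty_mask(self):
        out = classical_segment(_net_input(np.full((32, 32), 0.4)))
        assert out.area_px == 0
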