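"""V-NET: loss, architecture contracts, augmentation, split, training."""

import numpy as np
import pytest

from tmtvnet.vnet import (
    AugmentParams,
    TrainingCase,
    VnetConfig,
    augment,
    build_model,
    soft_dice_loss,
    split_dataset,
    train,
)
from tmtvnet.vnet import autograd as ag


class TestSoftDiceLoss:
    def test_identical_binary_masks_give_zero(self):
        m = (np.arange(27).reshape(3, 3, 3) % 4 == 0).astype(float)
        assert soft_dice_loss(m, m) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_masks_give_one(self):
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a[0, 0, 0] = 1.0
        b[2, 2, 2] = 1.0
        assert soft_dice_loss(a, b) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_against_binary_matches_formula(self):
        """10 voxels, 4 true, pred 0.5 everywhere:
        1 - 2*(0.5*4)/(5 + 4) = 5/9."""
        pred = np.full((1, 1, 10), 0.5)
        truth = np.zeros((1, 1, 10))
        truth[0, 0, :4] = 1.0
        assert soft_dice_loss(pred, truth) == pytest.approx(5 / 9, rel=1e-5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.random((2, 4, 4, 4))
            la, lb = soft_dice_loss(a, b), soft_dice_loss(b, a)
            assert la == pytest.approx(lb, abs=1e-9)
            assert 0.0 <= la <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestAutograd:
    def test_gradients_match_finite_differences(self):
        """End-to-end gradient check of the full op set on a tiny net."""
        rng = np.random.default_rng(0)
        model = build_model(VnetConfig(levels=2, base_channels=2, seed=0))
        x = rng.random((2, 4, 4, 4)).astype(np.float32)
        t = (rng.random((1, 4, 4, 4)) > 0.7).astype(np.float32)
        model.zero_grad()
        ag.soft_dice(model.forward(x), t).backward()

        def loss_at():
            return float(ag.soft_dice(model.forward(x), t).data)

        for name, p in model.parameters().items():
            flat = p.data.ravel()
            for idx in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps, orig = 1e-3, flat[idx]
                flat[idx] = orig + eps
                lp = loss_at()
                flat[idx] = orig - eps
                lm = loss_at()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert p.grad.ravel()[idx] == pytest.approx(numeric, abs=5e-4), name


class TestModel:
    def test_output_shape_matches_input(self):
        model = build_model(VnetConfig(levels=4, base_channels=8, seed=0))
        out = model.predict(np.zeros((2, 16, 16, 32), np.float32))
        assert out.shape == (16, 16, 32)

    def test_sigmoid_output_strictly_inside_unit_interval(self):
        model = build_model(VnetConfig(levels=2, base_channels=4, seed=1))
        out = model.predict(np.random.default_rng(0).random((2, 8, 8, 8)))
        assert 0.0 < out.min() and out.max() < 1.0

    def test_parameter_count_increases_with_base_channels(self):
        counts = [
            build_model(VnetConfig(levels=3, base_channels=c, seed=0)).n_parameters()
            for c in (4, 8, 16)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_channels_double_per_level(self):
        model = build_model(VnetConfig(levels=4, base_channels=8, seed=0))
        assert model._chans == [8, 16, 32, 64]

    def test_indivisible_shape_rejected(self):
        model = build_model(VnetConfig(levels=4, base_channels=8, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            model.predict(np.zeros((2, 12, 12, 12), np.float32))

    def test_state_dict_roundtrip(self):
        cfg = VnetConfig(levels=2, base_channels=4, seed=3)
        a, b = build_model(cfg), build_model(VnetConfig(levels=2, base_channels=4, seed=4))
        x = np.random.default_rng(0).random((2, 8, 8, 8)).astype(np.float32)
        assert not np.allclose(a.predict(x), b.predict(x))
        b.load_state_dict(a.state_dict())
        assert np.allclose(a.predict(x), b.predict(x))


class TestAugment:
    def _volumes(self, seed=0):
        rng = np.random.default_rng(seed)
        pet = rng.random((12, 12, 12)).astype(np.float32)
        ct = rng.random((12, 12, 12)).astype(np.float32)
        truth = (rng.random((12, 12, 12)) > 0.8).astype(np.float32)
        return pet, ct, truth

    def test_identity_parameters_change_nothing(self):
        pet, ct, truth = self._volumes()
        out = augment(pet, ct, truth, params=AugmentParams())
        for orig, new in zip((pet, ct, truth), out):
            assert np.allclose(orig, new, atol=1e-6)

    def test_same_seed_reproduces(self):
        pet, ct, truth = self._volumes()
        a = augment(pet, ct, truth, seed=5)
        b = augment(pet, ct, truth, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    @pytest.mark.parametrize("scale", [0.9, 1.1])
    def test_mask_volume_scales_with_cube_of_factor(self, scale):
        n = 32
        idx = np.indices((n, n, n)).astype(float)
        r = np.sqrt(((idx - (n - 1) / 2) ** 2).sum(0))
        truth = (r < 10).astype(np.float32)
        zeros = np.zeros_like(truth)
        _, _, out = augment(zeros, zeros, truth, params=AugmentParams(scale=scale))
        ratio = (out > 0.5).sum() / (truth > 0.5).sum()
        assert ratio == pytest.approx(scale**3, rel=0.2)

    def test_translation_moves_features(self):
        pet = np.zeros((16, 16, 16), np.float32)
        pet[8, 8, 8] = 1.0
        zeros = np.zeros_like(pet)
        params = AugmentParams(translation_mm=(8.0, 0.0, 0.0))
        out, _, _ = augment(pet, zeros, zeros, params=params, spacing_mm=(4, 4, 4))
        assert out[10, 8, 8] == pytest.approx(1.0, abs=1e-4)  # +2 voxels


class TestSplitDataset:
    def test_fractions_60_20_20(self):
        split = split_dataset(list(range(10)), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (6, 2, 2)

    def test_disjoint_and_exhaustive(self):
        ids = [f"case{i}" for i in range(23)]
        split = split_dataset(ids, seed=1)
        parts = [set(split.train), set(split.val), set(split.test)]
        assert sum(len(p) for p in parts) == 23
        assert set.union(*parts) == set(ids)

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(20)), seed=7)
        b = split_dataset(list(range(20)), seed=7)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)


class TestTrain:
    def _tiny_cases(self, n, seed=0):
        """High-contrast blob cases on an 8x8x8 grid (fast smoke training)."""
        rng = np.random.default_rng(seed)
        cases = []
        for i in range(n):
            target = np.zeros((8, 8, 8), np.float32)
            c = rng.integers(2, 6, size=3)
            target[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = 1.0
            pet = 0.03 + 0.4 * target + rng.normal(0, 0.01, target.shape)
            ct = np.full_like(target, 0.5)
            cases.append(TrainingCase(f"t{i}", np.stack([ct, pet.clip(0, 1)]), target))
        return cases

    def test_loss_decreases_and_history_has_epoch_length(self):
        cases = self._tiny_cases(6)
        cfg = VnetConfig(levels=2, base_channels=4, epochs=8, seed=0,
                         augment_per_case=0)
        state, hist = train(cases, cfg)
        assert len(hist["train_loss"]) == cfg.epochs
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_validation_checkpointing_returns_best_epoch(self):
        cases = self._tiny_cases(6)
        cfg = VnetConfig(levels=2, base_channels=4, epochs=5, seed=1,
                         augment_per_case=0)
        state, hist = train(cases[:4], cfg, val_cases=cases[4:])
        assert hist["best_loss"] == pytest.approx(
            min(v for v in hist["val_loss"] if v is not None)
        )

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            train(self._tiny_cases(1), VnetConfig(levels=2, base_channels=2))

    def test_weights_save_load_roundtrip(self, tmp_path):
        from tmtvnet.vnet import load_weights, save_weights

        cfg = VnetConfig(levels=2, base_channels=4, seed=2)
        model = build_model(cfg)
        path = tmp_path / "w.npz"
        save_weights(path, model.state_dict(), cfg)
        state, cfg2 = load_weights(path)
        assert cfg2 == cfg
        other = build_model(cfg2)
        other.load_state_dict(state)
        x = np.random.default_rng(0).random((2, 8, 8, 8)).astype(np.float32)
        assert np.allclose(model.predict(x), other.predict(x))
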