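"""Dice loss, sliding-window inference, subset ensembling, training loop."""

import numpy as np
import pytest

import dwiseg.segmentation as seg_mod
from dwiseg.segmentation import (
    EnsemblePrediction,
    ModelConfig,
    binarize,
    build_model,
    ensemble_predict,
    load_checkpoint,
    save_checkpoint,
    sliding_window_predict,
    soft_dice_loss,
    train,
    _soft_dice_grad,
)
from dwiseg.subsets import make_training_sampler
from tests.conftest import make_phantom_case


class TestSoftDice:
    def test_perfect_overlap_is_zero(self):
        t = (np.random.default_rng(0).random((4, 4, 4, 2)) > 0.5).astype(float)
        assert soft_dice_loss(t, t) < 1e-6

    def test_disjoint_masks_are_one(self):
        a = np.zeros((4, 4, 4, 1))
        b = np.zeros((4, 4, 4, 1))
        a[0, 0, 0, 0] = 1.0
        b[3, 3, 3, 0] = 1.0
        assert soft_dice_loss(a, b) == pytest.approx(1.0, abs=1e-5)

    def test_matches_literal_formula(self):
        rng = np.random.default_rng(1)
        pred = rng.random((4, 4, 4, 3))
        target = (rng.random((4, 4, 4, 3)) > 0.5).astype(float)
        eps = 1e-6
        per_label = []
        for c in range(3):
            p, t = pred[..., c], target[..., c]
            per_label.append(
                1 - (2 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps)
            )
        assert soft_dice_loss(pred, target) == pytest.approx(np.mean(per_label))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2, 2, 1)), np.zeros((2, 2, 2, 2)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        pred = rng.random((3, 3, 3, 2))
        target = (rng.random((3, 3, 3, 2)) > 0.5).astype(float)
        grad = _soft_dice_grad(pred, target)
        h = 1e-7
        for _ in range(10):
            idx = tuple(rng.integers(s) for s in pred.shape)
            p2 = pred.copy()
            p2[idx] += h
            num = (soft_dice_loss(p2, target) - soft_dice_loss(pred, target)) / h
            assert num == pytest.approx(float(grad[idx]), abs=1e-5)


class TestBinarize:
    def test_above_threshold_all_ones(self):
        assert binarize(np.full((2, 2, 2, 1), 0.6), 0.5).all()

    def test_strict_threshold_empty(self):
        assert not binarize(np.full((2, 2, 2, 1), 0.99), 1.0).any()

    def test_matches_elementwise_comparison(self):
        prob = np.random.default_rng(3).random((5, 5, 5, 2))
        np.testing.assert_array_equal(binarize(prob, 0.3), prob >= 0.3)


class _StubModel:
    """Stand-in model with a fixed or input-dependent response."""

    def __init__(self, out_ch, fn):
        self.out_ch = out_ch
        self._fn = fn

    def forward(self, x):
        return self._fn(x)


class TestSlidingWindow:
    def test_single_patch_equals_forward_pass(self):
        cfg = ModelConfig(patch_shape=(16, 16, 16), out_labels=2,
                          base_width=4, seed=0)
        model = build_model(cfg)
        x = np.random.default_rng(0).normal(size=(6, 16, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(
            sliding_window_predict(model, x, cfg.patch_shape),
            model.forward(x), atol=1e-6,
        )

    def test_constant_stub_is_exact_under_overlap(self):
        stub = _StubModel(2, lambda x: np.full((2,) + x.shape[1:], 0.25))
        x = np.zeros((1, 24, 24, 24))
        out = sliding_window_predict(stub, x, (16, 16, 16))
        np.testing.assert_allclose(out, 0.25, atol=1e-7)

    def test_overlap_average_matches_bookkeeping_oracle(self):
        """Each voxel equals the mean of the stub's patch responses
        covering it, tracked independently."""
        rng = np.random.default_rng(4)
        vol = rng.random((1, 20, 12, 12)).astype(np.float32)
        stub = _StubModel(1, lambda x: x * 2.0 + 1.0)
        patch = (8, 8, 8)
        got = sliding_window_predict(stub, vol, patch, overlap=0.5)
        acc = np.zeros_like(vol, dtype=float)
        cnt = np.zeros(vol.shape[1:])
        from dwiseg.segmentation import _tile_starts
        steps = [4, 4, 4]
        for ox in _tile_starts(20, 8, 4):
            for oy in _tile_starts(12, 8, 4):
                for oz in _tile_starts(12, 8, 4):
                    sl = (slice(None), slice(ox, ox + 8), slice(oy, oy + 8),
                          slice(oz, oz + 8))
                    acc[sl] += vol[sl] * 2.0 + 1.0
                    cnt[sl[1:]] += 1
        np.testing.assert_allclose(got, acc / cnt, atol=1e-6)

    def test_small_volume_padded_and_cropped(self):
        stub = _StubModel(1, lambda x: x.sum(axis=0, keepdims=True) * 0 + 0.5)
        out = sliding_window_predict(stub, np.zeros((1, 5, 5, 5)), (8, 8, 8))
        assert out.shape == (1, 5, 5, 5)


@pytest.fixture(scope="module")
def case():
    return make_phantom_case(seed=0, grid=16)


class TestEnsemble:
    def _config(self):
        return ModelConfig(patch_shape=(16, 16, 16), out_labels=2,
                           base_width=4, seed=0)

    def test_single_subset_mean_is_member(self, case):
        dwi, _ = case
        model = build_model(self._config())
        ens = ensemble_predict(model, dwi, self._config(), k=6, n=1, rng_seed=0)
        np.testing.assert_array_equal(ens.mean, ens.members[0])

    def test_mean_matches_recomputed_average(self, case):
        dwi, _ = case
        model = build_model(self._config())
        ens = ensemble_predict(model, dwi, self._config(), k=6, n=4, rng_seed=1)
        np.testing.assert_allclose(
            ens.mean, np.mean(ens.members, axis=0), atol=1e-6
        )
        assert len(ens.subsets) == 4

    def test_mean_permutation_invariant(self, case):
        dwi, _ = case
        model = build_model(self._config())
        ens = ensemble_predict(model, dwi, self._config(), k=6, n=3, rng_seed=2)
        perm = EnsemblePrediction(members=ens.members[::-1],
                                  subsets=ens.subsets[::-1])
        np.testing.assert_allclose(perm.mean, ens.mean, atol=1e-7)

    def test_inconsistent_stored_mean_rejected(self):
        m = [np.full((2, 2, 2, 1), 0.5)]
        with pytest.raises(ValueError, match="mean"):
            EnsemblePrediction(members=m, subsets=[None],
                               mean=np.full((2, 2, 2, 1), 0.9))


class TestTraining:
    def _tiny_setup(self, epochs=2, iters=5):
        cases = [make_phantom_case(seed=s, grid=16) for s in range(2)]
        cfg = ModelConfig(patch_shape=(16, 16, 16), out_labels=2, depth=2,
                          base_width=4, learning_rate=1e-3, epochs=epochs,
                          iters_per_epoch=iters, seed=1)
        model = build_model(cfg)
        sampler = make_training_sampler(cases[0][0].gtab, 6, 12, rng_seed=2)
        return model, cases, cfg, sampler

    def test_loss_decreases_on_single_tube(self, straight_tube_spec):
        from dwiseg.gradients import b0_normalize
        from dwiseg.phantom import simulate_dwi

        dwi, labels = simulate_dwi(straight_tube_spec)
        case = (b0_normalize(dwi), labels)
        cfg = ModelConfig(patch_shape=(24, 24, 24), out_labels=1, depth=2,
                          base_width=4, learning_rate=1e-3, epochs=4,
                          iters_per_epoch=50, seed=0)
        model = build_model(cfg)
        sampler = make_training_sampler(case[0].gtab, 6, 12, rng_seed=1)
        _, log = train(model, [case], [case], cfg, sampler)
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_two_runs_identical(self):
        logs = []
        for _ in range(2):
            model, cases, cfg, sampler = self._tiny_setup()
            _, log = train(model, cases[:1], cases[1:], cfg, sampler)
            logs.append(log)
        np.testing.assert_array_equal(logs[0]["train_loss"], logs[1]["train_loss"])
        np.testing.assert_array_equal(logs[0]["val_loss"], logs[1]["val_loss"])

    def test_plateau_halves_learning_rate(self, monkeypatch):
        """With the validation loss pinned to a constant, the schedule
        halves the learning rate after each patience window."""
        monkeypatch.setattr(seg_mod, "_validation_loss",
                            lambda *a, **k: 0.5)
        model, cases, cfg, sampler = self._tiny_setup(epochs=3, iters=2)
        cfg.lr_halve_patience = 1
        _, log = train(model, cases[:1], cases[1:], cfg, sampler)
        # the log records the rate used during each epoch: epoch 0 sets
        # the best value, each later plateau epoch halves the rate for
        # the next one
        assert log["lr"].tolist() == pytest.approx(
            [cfg.learning_rate, cfg.learning_rate, cfg.learning_rate / 2]
        )

    def test_empty_case_lists_rejected(self):
        model, cases, cfg, sampler = self._tiny_setup()
        with pytest.raises(ValueError):
            train(model, [], cases, cfg, sampler)


def test_checkpoint_roundtrip_preserves_predictions(tmp_path):
    cfg = ModelConfig(patch_shape=(16, 16, 16), out_labels=2, base_width=4,
                      seed=4)
    model = build_model(cfg)
    save_checkpoint(model, cfg, tmp_path / "model.npz",
                    extra={"note": "test"})
    back, cfg_back = load_checkpoint(tmp_path / "model.npz")
    assert cfg_back == cfg
    x = np.random.default_rng(5).normal(size=(6, 16, 16, 16)).astype(np.float32)
    np.testing.assert_allclose(back.forward(x), model.forward(x), atol=1e-7)
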