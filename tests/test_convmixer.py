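import numpy as np
import pytest

from coromix.convmixer import (
    BN_EPS,
    ConfigurationError,
    DegenerateTrainingSetError,
    MIMSConvMixer,
    ModelConfig,
    TrainOptions,
    build_model,
    count_parameters,
    predict,
    train_model,
)

MICRO = ModelConfig(input_size=16, patch_sizes=(8,), hidden=2, kernel=3,
                    depth=1, embed_dim=8)


def _inputs(rng, n, config=MICRO):
    return rng.random((n, config.n_leads, config.input_size, config.input_size, 3))


class TestConfig:
    def test_indivisible_patch_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_size=64, patch_sizes=(24,))

    def test_branch_and_concat_dimensions(self):
        cfg = ModelConfig(hidden=750, patch_sizes=(16, 8))
        assert cfg.n_branches == 24
        assert cfg.concat_dim == 18000  # 12 leads x 2 scales x 750

    def test_patch_grid_sizes(self, rng):
        model = build_model(ModelConfig(hidden=2, depth=1), seed=0)
        x = rng.random((1, 64, 64, 3))
        _, cache16 = model._branch_forward(x, 0, train=False)   # P=16
        _, cache8 = model._branch_forward(x, 12, train=False)   # P=8
        assert cache16["grid"] == 4 and cache8["grid"] == 8


class TestParameterCount:
    def test_hand_counted_micro_branch(self):
        """patch 16*16*3*2+2, depthwise 3*3*2+2, pointwise 2*2+2, 3 BN pairs."""
        model = build_model(
            ModelConfig(input_size=64, patch_sizes=(16,), hidden=2, depth=1), seed=0
        )
        assert model.branch_parameter_count(0) == 1576

    def test_depth_adds_parameters_linearly(self):
        def total(depth):
            return count_parameters(
                build_model(ModelConfig(input_size=16, patch_sizes=(8,), hidden=3,
                                        depth=depth, embed_dim=4), seed=0)
            )

        d1, d2, d3 = total(1), total(2), total(3)
        assert d2 - d1 == d3 - d2 > 0

    def test_count_invariant_to_input_size(self):
        a = count_parameters(build_model(
            ModelConfig(input_size=16, patch_sizes=(8,), hidden=2, embed_dim=4),
            seed=0))
        b = count_parameters(build_model(
            ModelConfig(input_size=32, patch_sizes=(8,), hidden=2, embed_dim=4),
            seed=0))
        assert a == b


class TestForward:
    def test_softmax_normalization_on_random_inputs(self, rng):
        model = build_model(MICRO, seed=3)
        probs = model.predict_proba(_inputs(rng, 200))
        assert probs.shape == (200, 7)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_input_shape_rejected(self, rng):
        model = build_model(MICRO, seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model.predict_proba(rng.random((2, 12, 8, 8, 3)))

    def test_residual_reduces_depthwise_stage_to_identity(self, rng):
        """Zeroed depthwise kernels + neutral BN make the residual stage an
        exact pass-through (the pointwise stage has no residual path)."""
        model = build_model(MICRO, seed=0)
        br, st = model.branches[0], model.bn_states[0]
        blk, bst = br["blocks"][0], st["blocks"][0]
        blk["dw_W"][...] = 0.0
        blk["dw_b"][...] = 0.0
        blk["bn1"]["gamma"][...] = 1.0
        blk["bn1"]["beta"][...] = 0.0
        bst["bn1"]["mean"][...] = 0.0
        bst["bn1"]["var"][...] = 1.0 - BN_EPS
        x = rng.random((3, 16, 16, 3))
        _, cache = model._branch_forward(x, 0, train=False)
        bc = cache["blocks"][0]
        np.testing.assert_array_equal(bc["t"], bc["x_in"])

    def test_scale_branch_permutation_symmetry(self, rng):
        """Swapping the two scale branch sets (weights, BN state and the
        matching fc_embed blocks) leaves predictions unchanged."""
        cfg = ModelConfig(input_size=16, patch_sizes=(8, 4), hidden=3, depth=1,
                          embed_dim=6)
        m1 = build_model(cfg, seed=5)
        cfg_swapped = ModelConfig(input_size=16, patch_sizes=(4, 8), hidden=3,
                                  depth=1, embed_dim=6)
        m2 = build_model(cfg_swapped, seed=5)
        n = cfg.n_leads
        H = cfg.hidden
        perm = list(range(n, 2 * n)) + list(range(n))  # swap scale blocks
        for dst, src in enumerate(perm):
            m2.branches[dst] = m1.branches[src]
            m2.bn_states[dst] = m1.bn_states[src]
        rows = np.concatenate([np.arange(b * H, (b + 1) * H) for b in perm])
        m2.head["emb_W"] = m1.head["emb_W"][rows]
        m2.head["emb_b"] = m1.head["emb_b"]
        m2.head["out_W"] = m1.head["out_W"]
        m2.head["out_b"] = m1.head["out_b"]
        X = _inputs(rng, 4)
        np.testing.assert_allclose(
            m1.predict_proba(X), m2.predict_proba(X), atol=1e-12
        )


class TestGradients:
    def test_numerical_gradient_agreement(self, rng):
        """Analytic backprop matches central differences to < 1e-4."""
        model = build_model(MICRO, seed=7)
        X = _inputs(rng, 3)
        y = np.array([0, 4, 6])
        _, _, grads = model.loss_and_grads(X, y)
        params = model.parameters()
        check_rng = np.random.default_rng(0)
        worst = 0.0
        for name, arr in params.items():
            flat = arr.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                eps = 1e-6
                old = flat[i]
                flat[i] = old + eps
                lp = model.loss_and_grads(X, y)[0]
                flat[i] = old - eps
                lm = model.loss_and_grads(X, y)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
        assert worst < 1e-4


class TestTraining:
    def test_loss_decreases_on_learnable_set(self, rng):
        """Class-dependent image means, tiny model: final loss < initial."""
        n_per = 6
        X = rng.random((7 * n_per, 12, 16, 16, 3))
        y = np.repeat(np.arange(7), n_per)
        X += 0.3 * (y[:, None, None, None, None] / 7.0)
        model = build_model(MICRO, seed=0)
        hist = train_model(model, X, y,
                           TrainOptions(epochs=5, minibatch=8, seed=0,
                                        validation_fraction=0.0))
        assert np.mean(hist.loss[-3:]) < hist.loss[0]
        assert model.trained

    def test_zero_learning_rate_freezes_parameters(self, rng):
        model = build_model(MICRO, seed=2)
        before = {k: v.copy() for k, v in model.parameters().items()}
        X = _inputs(rng, 8)
        y = np.arange(8) % 7
        train_model(model, X, y,
                    TrainOptions(epochs=1, minibatch=4, initial_lr=0.0, seed=0,
                                 validation_fraction=0.0))
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_same_seed_reproduces_history(self, rng):
        X = _inputs(rng, 10)
        y = np.arange(10) % 7
        opts = TrainOptions(epochs=2, minibatch=4, seed=11,
                            validation_fraction=0.2, validation_frequency=2)
        h1 = train_model(build_model(MICRO, seed=1), X, y, opts)
        h2 = train_model(build_model(MICRO, seed=1), X, y, opts)
        assert h1.loss == h2.loss
        assert h1.val_loss == h2.val_loss

    def test_single_class_rejected(self, rng):
        model = build_model(MICRO, seed=0)
        with pytest.raises(DegenerateTrainingSetError):
            train_model(model, _inputs(rng, 4), np.zeros(4, dtype=int),
                        TrainOptions(epochs=1, minibatch=2, seed=0))


class TestFeatures:
    def test_embedding_shape_and_determinism(self, rng):
        model = build_model(MICRO, seed=0)
        X = _inputs(rng, 5)
        F1 = model.extract_features(X)
        F2 = model.extract_features(X)
        assert F1.shape == (5, 8)
        np.testing.assert_array_equal(F1, F2)

    def test_identical_records_identical_rows(self, rng):
        model = build_model(MICRO, seed=0)
        X = _inputs(rng, 2)
        X[1] = X[0]
        F = model.extract_features(X)
        np.testing.assert_array_equal(F[0], F[1])

    def test_features_are_unconstrained_pre_softmax_activations(self, rng):
        model = build_model(MICRO, seed=0)
        F = model.extract_features(_inputs(rng, 20))
        assert F.min() < 0 or F.max() > 1


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model(MICRO, seed=4)
        X = _inputs(rng, 6)
        y = np.arange(6) % 7
        train_model(model, X, y,
                    TrainOptions(epochs=1, minibatch=3, seed=0,
                                 validation_fraction=0.0))
        path = tmp_path / "m.npz"
        model.save(path)
        back = MIMSConvMixer.load(path)
        assert back.trained
        np.testing.assert_array_equal(
            model.predict_proba(X), back.predict_proba(X)
        )

    def test_predict_single_record(self, rng):
        model = build_model(MICRO, seed=0)
        p = predict(model, rng.random((12, 16, 16, 3)))
        assert p.shape == (7,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
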