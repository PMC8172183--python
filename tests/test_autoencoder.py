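import numpy as np
import pytest

from eegstress.autoencoder import (
    AEArchitecture,
    AutoencoderModel,
    TrainConfig,
    _backprop,
    _init_params,
    encode,
    gradient_check,
    load_model,
    rmse_loss,
    save_model,
    train,
)
from eegstress.features import WindowedFeatures


def make_features(X, feature_set="power"):
    n = X.shape[0]
    return WindowedFeatures(
        feature_set=feature_set, matrix=X,
        labels=np.array(["baseline"] * n, dtype=object),
        subject_ids=np.array(["S0"] * n, dtype=object),
        groups=np.array(["control"] * n, dtype=object),
        window_indices=np.arange(n),
        column_names=tuple(f"f{i}" for i in range(X.shape[1])),
    )


def subspace_data(n=400, d=9, rank=2, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    basis = rng.standard_normal((rank, d))
    coeffs = rng.standard_normal((n, rank))
    return coeffs @ basis + noise * rng.standard_normal((n, d))


class TestRmseLoss:
    def test_zero_at_perfect_reconstruction(self):
        x = np.arange(12.0).reshape(4, 3)
        assert rmse_loss(x, x) == 0.0

    def test_direct_substitution(self):
        assert rmse_loss(np.array([1.0, 2.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(5 / 2), abs=1e-15)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(0)
        x, xp = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        acc = 0.0
        for i in range(5):
            for j in range(3):
                acc += (x[i, j] - xp[i, j]) ** 2
        expected = np.sqrt(acc / 15)
        assert abs(rmse_loss(x, xp) - expected) < 1e-12 * expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rmse_loss(np.zeros(3), np.zeros(4))


class TestGradientCheck:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_backprop_matches_finite_differences(self, seed):
        assert gradient_check(seed=seed) < 1e-5

    def test_zero_residual_gives_zero_gradients(self):
        """Zero input through zero biases and an odd activation reconstructs
        exactly, so the (guarded) RMSE gradient is zero everywhere."""
        arch = AEArchitecture(input_dim=2, encoder_widths=(3,), hidden_activation="tanh")
        rng = np.random.default_rng(0)
        weights, biases = _init_params(arch, rng)
        model = AutoencoderModel(arch=arch, weights=weights, biases=biases,
                                 mean=np.zeros(2), scale=np.ones(2))
        loss, gW, gb = _backprop(model, np.zeros((4, 2)))
        assert loss == 0.0
        assert all(np.all(g == 0) for g in gW + gb)


class TestTraining:
    def test_low_rank_data_rmse_drops_below_quarter(self):
        feats = make_features(subspace_data())
        model = train(feats, hyper=TrainConfig(seed=0))
        trace = model.training_trace
        assert min(trace) < 0.25 * trace[0]

    def test_linear_limit_recovers_identity(self):
        """Identity activations, latent >= input dim, noiseless data:
        reconstruction RMSE falls below 1% of the data sd."""
        X = subspace_data(n=300, d=3, rank=3, noise=0.0, seed=1)
        arch = AEArchitecture(input_dim=3, encoder_widths=(4,),
                              hidden_activation="identity")
        model = train(X, arch, TrainConfig(lr=0.05, max_epochs=1000, patience=200, seed=0))
        Xs = model.standardize(X)
        final = rmse_loss(Xs, model.reconstruct(Xs))
        assert final < 0.01 * Xs.std()

    def test_zero_lr_leaves_weights_unchanged(self):
        X = subspace_data(n=50)
        arch = AEArchitecture(input_dim=9, encoder_widths=(4,))
        rng = np.random.default_rng(3)
        ref_w, _ = _init_params(arch, rng)
        model = train(X, arch, TrainConfig(lr=0.0, max_epochs=5, seed=3))
        for W, Wref in zip(model.weights, ref_w):
            np.testing.assert_array_equal(W, Wref)
        assert len(set(np.round(model.training_trace, 12))) == 1

    def test_same_seed_identical_weights(self):
        X = subspace_data(n=100)
        a = train(X, hyper=TrainConfig(seed=5, max_epochs=10))
        b = train(X, hyper=TrainConfig(seed=5, max_epochs=10))
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)

    def test_returned_model_is_best_epoch(self):
        X = subspace_data(n=100)
        model = train(X, hyper=TrainConfig(seed=2, max_epochs=30))
        Xs = model.standardize(X)
        final = rmse_loss(Xs, model.reconstruct(Xs))
        assert final <= min(model.training_trace) + 1e-12

    def test_divergence_reported_with_epoch_and_lr(self):
        # linear dynamics at an absurd step size grow without bound
        X = subspace_data(n=50, noise=1.0)
        arch = AEArchitecture(input_dim=9, encoder_widths=(4,),
                              hidden_activation="identity")
        with pytest.raises(FloatingPointError, match="lr"), np.errstate(all="ignore"):
            train(X, arch, TrainConfig(lr=1e8, max_epochs=50, seed=0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input_dim"):
            train(subspace_data(d=9), AEArchitecture(input_dim=5))


class TestEncode:
    def test_latent_shape_and_metadata(self):
        feats = make_features(subspace_data(n=200))
        model = train(feats, hyper=TrainConfig(seed=0, max_epochs=5))
        latent = encode(model, feats)
        assert latent.matrix.shape == (200, 50)
        assert latent.feature_set == "power_latent"
        assert list(latent.labels) == list(feats.labels)

    def test_inference_is_deterministic(self):
        feats = make_features(subspace_data(n=50))
        model = train(feats, hyper=TrainConfig(seed=0, max_epochs=3))
        np.testing.assert_array_equal(encode(model, feats).matrix,
                                      encode(model, feats).matrix)

    def test_row_permutation_equivariance(self):
        feats = make_features(subspace_data(n=60))
        model = train(feats, hyper=TrainConfig(seed=0, max_epochs=3))
        perm = np.random.default_rng(1).permutation(60)
        a = encode(model, feats, restandardize=False).matrix[perm]
        b = encode(model, feats.subset(perm), restandardize=False).matrix
        np.testing.assert_allclose(a, b)

    def test_input_dim_mismatch_rejected(self):
        model = train(subspace_data(d=9), hyper=TrainConfig(seed=0, max_epochs=2))
        with pytest.raises(ValueError, match="input features"):
            encode(model, make_features(subspace_data(d=5)))


def test_save_load_round_trip(tmp_path):
    feats = make_features(subspace_data(n=40))
    model = train(feats, hyper=TrainConfig(seed=0, max_epochs=3))
    save_model(model, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    np.testing.assert_allclose(back.reconstruct(model.standardize(feats.matrix)),
                               model.reconstruct(model.standardize(feats.matrix)))
    assert back.arch == model.arch
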