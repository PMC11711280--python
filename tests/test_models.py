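"""Losses, training, encode/reconstruct, and model persistence."""

import math

import numpy as np
import pytest

from tracebench import (
    LabeledMatrix,
    ModelConfig,
    TrainedModel,
    cross_entropy_loss,
    fit,
    reconstruction_loss,
    trace_objective,
)
from conftest import fast_config


class TestLosses:
    def test_mse_identity_and_constants(self):
        X = np.zeros((2, 2))
        assert reconstruction_loss(X, X) == 0.0
        assert reconstruction_loss(X, np.ones((2, 2))) == 1.0

    def test_mse_elementwise_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Xh = np.array([[1.0, 0.0], [0.0, 4.0]])
        brute = sum((a - b) ** 2 for a, b in zip(X.ravel(), Xh.ravel())) / 4
        assert brute == 3.25
        assert reconstruction_loss(X, Xh) == pytest.approx(brute, abs=1e-15)

    def test_mse_symmetric(self):
        rng = np.random.default_rng(0)
        A, B = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        assert reconstruction_loss(A, B) == reconstruction_loss(B, A)

    def test_mse_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_cross_entropy_closed_forms(self):
        eye = np.eye(3)
        assert cross_entropy_loss(eye, eye) == pytest.approx(0.0, abs=1e-10)
        uniform = np.full((4, 10), 0.1)
        onehot = np.zeros((4, 10))
        onehot[np.arange(4), [0, 3, 5, 9]] = 1
        assert cross_entropy_loss(onehot, uniform) == pytest.approx(math.log(10), abs=1e-12)
        y = np.array([[1.0, 0.0]])
        yh = np.array([[0.8, 0.2]])
        assert cross_entropy_loss(y, yh) == pytest.approx(-math.log(0.8), abs=1e-12)

    def test_cross_entropy_clipping_never_infinite(self):
        y = np.array([[1.0, 0.0]])
        yh = np.array([[0.0, 1.0]])
        val = cross_entropy_loss(y, yh)
        assert np.isfinite(val) and val > 20  # -log(1e-12) ~ 27.6

    def test_objective_arithmetic(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Xh = np.array([[1.0, 0.0], [0.0, 4.0]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        yh = np.array([[0.8, 0.2], [0.8, 0.2]])
        expected = 3.25 + 2.0 * (-math.log(0.8))
        assert trace_objective(X, Xh, y, yh, alpha=2.0) == pytest.approx(expected, abs=1e-12)
        assert trace_objective(X, Xh, y, yh, alpha=0.0) == reconstruction_loss(X, Xh)

    def test_objective_negative_alpha_rejected(self):
        X = np.zeros((1, 1))
        y = np.array([[1.0]])
        with pytest.raises(ValueError, match="alpha"):
            trace_objective(X, X, y, y, alpha=-0.5)


class TestConfig:
    def test_hidden_dim_defaults(self):
        assert ModelConfig(family="AE", input_dim=784, bottleneck_dim=2).hidden_dim == 512
        assert ModelConfig(family="AE", input_dim=50, bottleneck_dim=2).hidden_dim == 50
        assert ModelConfig(family="AE", input_dim=2000, bottleneck_dim=2).hidden_dim == 1024

    def test_bottleneck_must_fit(self):
        with pytest.raises(ValueError, match="bottleneck"):
            ModelConfig(family="AE", input_dim=5, bottleneck_dim=6)

    def test_trace_needs_class_count(self):
        with pytest.raises(ValueError, match="class_count"):
            ModelConfig(family="TRACE", input_dim=5, bottleneck_dim=2)


class TestPCA:
    def test_lossless_at_rank(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 12))
        data = LabeledMatrix(X, np.repeat(np.arange(4), 10), 4)
        model = fit(ModelConfig(family="PCA", input_dim=12, bottleneck_dim=3), data)
        assert reconstruction_loss(X, model.reconstruct(X)) <= 1e-10

    def test_full_rank_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 6))
        data = LabeledMatrix(X, np.repeat([0, 1], 10), 2)
        model = fit(ModelConfig(family="PCA", input_dim=6, bottleneck_dim=6), data)
        np.testing.assert_allclose(model.decode(model.encode(X)), X, atol=1e-10)

    def test_reconstruction_loss_nonincreasing_in_d(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 10))
        data = LabeledMatrix(X, np.repeat(np.arange(5), 10), 5)
        losses = []
        for d in (1, 2, 4, 7, 10):
            m = fit(ModelConfig(family="PCA", input_dim=10, bottleneck_dim=d), data)
            losses.append(reconstruction_loss(X, m.reconstruct(X)))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_deterministic_refit(self, small_synthetic):
        train, test = small_synthetic
        cfg = ModelConfig(family="PCA", input_dim=30, bottleneck_dim=3)
        a = fit(cfg, train).encode(test.features)
        b = fit(cfg, train).encode(test.features)
        np.testing.assert_array_equal(a, b)


class TestForwardPass:
    def _scalar_model(self):
        """1-1-1-1-1 network with hand-set weights for a by-hand forward pass."""
        cfg = ModelConfig(family="AE", input_dim=1, bottleneck_dim=1, hidden_dim=1,
                          output_activation="linear")
        params = {
            "W1": np.array([[0.5]]), "b1": np.array([0.1]),
            "W2": np.array([[-1.2]]), "b2": np.array([0.3]),
            "W3": np.array([[0.7]]), "b3": np.array([-0.2]),
            "W4": np.array([[2.0]]), "b4": np.array([0.05]),
        }
        return TrainedModel(config=cfg, params=params, output_activation="linear")

    def test_hand_computed_tanh_chain(self):
        model = self._scalar_model()
        x = 0.8
        h1 = math.tanh(0.5 * x + 0.1)
        z = -1.2 * h1 + 0.3
        h2 = math.tanh(0.7 * z - 0.2)
        xhat = 2.0 * h2 + 0.05
        np.testing.assert_allclose(model.encode([[x]]), [[z]], atol=1e-15)
        np.testing.assert_allclose(model.reconstruct([[x]]), [[xhat]], atol=1e-15)

    def test_zero_weights_zero_bottleneck(self):
        model = self._scalar_model()
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        np.testing.assert_array_equal(model.encode([[3.0]]), [[0.0]])

    def test_width_mismatch_rejected(self):
        model = self._scalar_model()
        with pytest.raises(ValueError, match="width"):
            model.encode(np.zeros((2, 3)))


class TestTraining:
    def test_alpha_zero_matches_ae_bitwise(self, small_synthetic):
        train, _ = small_synthetic
        kwargs = dict(n=30, d=2, k=4, epochs=10, seed=11)
        trace = fit(fast_config("TRACE", alpha=0.0, **kwargs), train)
        ae = fit(fast_config("AE", **kwargs), train)
        assert trace.loss_trace == ae.loss_trace
        for key in ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4"):
            np.testing.assert_array_equal(trace.params[key], ae.params[key])

    @pytest.mark.parametrize("family", ["TRACE", "AE", "VAE"])
    def test_loss_finite_and_decreasing(self, family, small_synthetic):
        train, _ = small_synthetic
        model = fit(fast_config(family, n=30, epochs=20), train)
        trace = np.asarray(model.loss_trace)
        assert np.all(np.isfinite(trace))
        assert trace[-1] < trace[0]

    @pytest.mark.parametrize("family", ["TRACE", "AE", "VAE"])
    def test_seed_reproducible_fit(self, family, small_synthetic):
        train, test = small_synthetic
        a = fit(fast_config(family, n=30, epochs=5, seed=3), train)
        b = fit(fast_config(family, n=30, epochs=5, seed=3), train)
        assert a.loss_trace == b.loss_trace
        np.testing.assert_array_equal(a.encode(test.features), b.encode(test.features))

    def test_trace_separates_well_separated_classes(self, small_synthetic):
        from tracebench import posthoc_classifier_accuracy
        train, test = small_synthetic
        model = fit(fast_config("TRACE", n=30, d=2, epochs=30, seed=5), train)
        acc = posthoc_classifier_accuracy(
            model.encode(train.features), train.labels,
            model.encode(test.features), test.labels,
        )
        assert acc > 0.9

    def test_classifier_head_outputs_probabilities(self, small_synthetic):
        train, test = small_synthetic
        model = fit(fast_config("TRACE", n=30, epochs=5), train)
        probs = model.predict_proba(test.features)
        assert probs.shape == (test.n_trials, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert probs.min() >= 0

    def test_sigmoid_output_for_unit_interval_data(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(40, 8))
        data = LabeledMatrix(X, np.repeat([0, 1], 20), 2)
        model = fit(ModelConfig(family="AE", input_dim=8, bottleneck_dim=2,
                                epochs=3, seed=0), data)
        assert model.output_activation == "sigmoid"
        recon = model.reconstruct(X)
        assert recon.min() >= 0 and recon.max() <= 1

    def test_vae_encode_is_deterministic_posterior_mean(self, small_synthetic):
        train, test = small_synthetic
        model = fit(fast_config("VAE", n=30, epochs=5), train)
        np.testing.assert_array_equal(model.encode(test.features),
                                      model.encode(test.features))

    def test_mismatched_width_rejected(self, small_synthetic):
        train, _ = small_synthetic
        with pytest.raises(ValueError, match="width|input_dim"):
            fit(fast_config("AE", n=29), train)


class TestPersistence:
    @pytest.mark.parametrize("family", ["TRACE", "AE", "VAE", "PCA"])
    def test_save_load_roundtrip(self, family, small_synthetic, tmp_path):
        train, test = small_synthetic
        model = fit(fast_config(family, n=30, epochs=3), train)
        model.save(tmp_path / family)
        loaded = TrainedModel.load(tmp_path / family)
        assert loaded.family == family
        np.testing.assert_array_equal(loaded.encode(test.features),
                                      model.encode(test.features))
        np.testing.assert_array_equal(loaded.reconstruct(test.features),
                                      model.reconstruct(test.features))
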