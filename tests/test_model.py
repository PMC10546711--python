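"""Classifier architecture, gradients, dropout semantics and training behaviour."""

import math

import numpy as np
import pytest

from seqdesign import synthetic
from seqdesign.model import (
    ModelConfig,
    ModelParams,
    cross_entropy,
    forward,
    init_model,
    loss_and_gradients,
    parameter_count,
    train,
)


class TestArchitecture:
    def test_default_shapes(self):
        params = init_model(ModelConfig())
        assert [w.shape for w in params.weights] == [
            (180, 64), (64, 64), (64, 64), (64, 20),
        ]
        assert [b.shape for b in params.biases] == [(64,), (64,), (64,), (20,)]

    def test_parameter_count_closed_form(self):
        """Count equals the independently summed fan-in*fan-out + bias terms."""
        config = ModelConfig()
        dims = [180, 64, 64, 64, 20]
        expected = sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))
        assert parameter_count(config) == expected == 21204

    def test_init_deterministic(self):
        a = init_model(ModelConfig(seed=9))
        b = init_model(ModelConfig(seed=9))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_layers=(0,))
        with pytest.raises(ValueError):
            ModelConfig(dropout_p=1.0)


class TestForward:
    def test_rows_sum_to_one(self, rng):
        params = init_model(ModelConfig(seed=0))
        probs = forward(params, rng.normal(size=(17, 180)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs > 0).all() and (probs < 1).all()

    def test_zero_parameters_give_uniform(self, rng):
        params = init_model(ModelConfig(seed=0))
        for w in params.weights:
            w[:] = 0
        for b in params.biases:
            b[:] = 0
        probs = forward(params, rng.normal(size=(5, 180)))
        np.testing.assert_allclose(probs, 1.0 / 20, atol=1e-12)

    def test_eval_mode_deterministic(self, rng):
        params = init_model(ModelConfig(seed=1))
        x = rng.normal(size=(8, 180))
        np.testing.assert_array_equal(forward(params, x), forward(params, x))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            forward(init_model(ModelConfig()), rng.normal(size=(4, 33)))

    def test_dropout_expectation_matches_eval(self, rng):
        """Inverted dropout: averaged train-mode activations equal eval-mode ones."""
        params = init_model(ModelConfig(input_dim=10, hidden_layers=(16,), seed=2))
        x = rng.normal(size=(3, 10))
        eval_cache = []
        forward(params, x, train_mode=False, _cache=eval_cache)
        eval_hidden = eval_cache[1][0]  # input fed to the output layer
        acc = np.zeros_like(eval_hidden)
        n_draws = 20000
        for _ in range(n_draws):
            cache = []
            forward(params, x, train_mode=True, rng=rng, _cache=cache)
            acc += cache[1][0]
        mc_error = 3 * np.abs(eval_hidden).max() / math.sqrt(n_draws)
        np.testing.assert_allclose(acc / n_draws, eval_hidden, atol=max(0.05, mc_error))


class TestCrossEntropy:
    def test_confident_correct_prediction(self):
        probs = np.full((1, 20), 1e-9)
        probs[0, 3] = 1 - 19e-9
        assert cross_entropy(probs, [3]) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_is_ln20(self):
        probs = np.full((4, 20), 1 / 20)
        assert cross_entropy(probs, [0, 5, 10, 19]) == pytest.approx(math.log(20))

    def test_hand_computed_two_sample_batch(self):
        """Independent arithmetic: mean of -ln p_true over two rows."""
        p1 = np.array([0.7] + [0.3 / 19] * 19)
        p2 = np.array([0.05] * 19 + [0.05])
        p2[4] = 1 - 0.05 * 19
        expected = -(math.log(0.7) + math.log(p2[4])) / 2
        assert cross_entropy(np.stack([p1, p2]), [0, 4]) == pytest.approx(expected)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Central differences on a 5-sample batch agree to 1e-4 relative error."""
        config = ModelConfig(input_dim=7, hidden_layers=(6, 5), dropout_p=0.0, seed=3)
        params = init_model(config)
        x = rng.normal(size=(5, 7))
        y = rng.integers(0, 20, size=5)
        _, grad_w, grad_b = loss_and_gradients(params, x, y)
        h = 1e-6
        for arrays, grads in ((params.weights, grad_w), (params.biases, grad_b)):
            for arr, grad in zip(arrays, grads):
                flat = arr.reshape(-1)
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    up, _, _ = loss_and_gradients(params, x, y)
                    flat[idx] = orig - h
                    down, _, _ = loss_and_gradients(params, x, y)
                    flat[idx] = orig
                    numeric = (up - down) / (2 * h)
                    denom = max(abs(numeric), abs(grad.reshape(-1)[idx]), 1e-8)
                    assert abs(numeric - grad.reshape(-1)[idx]) / denom < 1e-4


@pytest.fixture(scope="module")
def dataset():
    fsets = synthetic.standard_dataset(n_chains=20, chain_length=30, seed=11)
    X, y = synthetic.pool_features(fsets)
    rng = np.random.default_rng(11)
    perm = rng.permutation(len(y))
    n_val = len(y) // 10
    return X[perm[n_val:]], y[perm[n_val:]], X[perm[:n_val]], y[perm[:n_val]]


class TestTraining:
    def test_early_descent(self, dataset):
        """Training loss drops over the first epochs of the learnable problem."""
        X_tr, y_tr, X_va, y_va = dataset
        drops = 0
        for seed in (0, 1, 2):
            params = train(X_tr, y_tr, X_va, y_va, ModelConfig(max_epochs=2, seed=seed))
            losses = params.history["train_loss"]
            drops += losses[1] <= losses[0]
        assert drops >= 2  # allow one stochastic violation over 3 seeds

    def test_learns_geometry_rule(self, dataset):
        X_tr, y_tr, X_va, y_va = dataset
        params = train(X_tr, y_tr, X_va, y_va, ModelConfig(max_epochs=50, seed=0))
        probs = forward(params, X_tr)
        assert np.mean(probs.argmax(axis=1) == y_tr) >= 0.95

    def test_deterministic_training(self, dataset):
        X_tr, y_tr, X_va, y_va = dataset
        config = ModelConfig(max_epochs=3, seed=4)
        a = train(X_tr, y_tr, X_va, y_va, config)
        b = train(X_tr, y_tr, X_va, y_va, config)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.history["val_loss"], b.history["val_loss"])

    def test_history_one_row_per_epoch(self, dataset):
        X_tr, y_tr, X_va, y_va = dataset
        params = train(X_tr, y_tr, X_va, y_va, ModelConfig(max_epochs=5, seed=0))
        assert len(params.history["epoch"]) == 5

    def test_serialization_round_trip(self, tmp_path, dataset):
        X_tr, y_tr, X_va, y_va = dataset
        params = train(X_tr, y_tr, X_va, y_va, ModelConfig(max_epochs=2, seed=0))
        path = tmp_path / "m.npz"
        params.save(path)
        back = ModelParams.load(path)
        for wa, wb in zip(params.weights, back.weights):
            np.testing.assert_array_equal(wa, wb)
        assert back.config == params.config
        np.testing.assert_array_equal(
            back.history["val_loss"], params.history["val_loss"]
        )
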