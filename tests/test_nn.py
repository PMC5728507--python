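"""Unit and property tests for the MLP and its mini-batch SGD trainer."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import swarmtune as st
from swarmtune.nn import ShapeError, _loss_and_grads


def tiny_model(layer_sizes, task="classification", seed=0):
    return st.init_mlp(layer_sizes, task=task, seed=seed)


class TestForwardLayer:
    @pytest.mark.parametrize(
        "inputs, weights, bias, activation, expected",
        [
            ([1.0, 1.0], [[0.0], [0.0]], [0.0], "tanh", 0.0),
            ([1.0, 1.0], [[0.5], [0.5]], [0.0], "tanh", np.tanh(1.0)),  # 0.76159...
            ([2.0], [[0.0]], [10.0], "sigmoid", 1.0 / (1.0 + np.exp(-10.0))),
        ],
    )
    def test_hand_evaluated_neurons(self, inputs, weights, bias, activation, expected):
        out = st.forward_layer(
            np.array(inputs), np.array(weights), np.array(bias), activation
        )
        assert out == pytest.approx(expected, abs=1e-6)

    def test_tanh_range_and_sigmoid_range(self, rng):
        x = rng.normal(size=(20, 5))
        w = rng.normal(size=(5, 4))
        b = rng.normal(size=4)
        t = st.forward_layer(x, w, b, "tanh")
        s = st.forward_layer(x, w, b, "sigmoid")
        assert np.all((t > -1) & (t < 1))
        assert np.all((s > 0) & (s < 1))

    def test_dimension_mismatch_names_layer(self):
        with pytest.raises(ShapeError, match="layer 3"):
            st.forward_layer(np.ones(3), np.ones((2, 2)), np.zeros(2), "tanh", layer_index=3)


class TestLosses:
    def test_mse_zero_residual_both_variants(self, rng):
        y = rng.normal(size=(6, 3))
        assert st.mse(y, y, "mean") == 0.0
        assert st.mse(y, y, "half_sum") == 0.0

    def test_mse_single_sample_variants(self):
        actual, predicted = np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])
        assert st.mse(actual, predicted, "mean") == pytest.approx(1.0)
        assert st.mse(actual, predicted, "half_sum") == pytest.approx(0.5)

    def test_mse_empty_rejected(self):
        with pytest.raises(ValueError):
            st.mse(np.empty((0, 2)), np.empty((0, 2)))

    @given(hst.integers(min_value=1, max_value=6), hst.integers(min_value=0, max_value=99))
    def test_mse_variants_related_by_n_over_2(self, n, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, n, 3))
        assert st.mse(a, b, "half_sum") == pytest.approx(
            st.mse(a, b, "mean") * n / 2
        )

    @pytest.mark.parametrize(
        "probs, labels, expected",
        [
            ([[1.0, 0.0], [0.0, 1.0]], [0, 1], 0.0),
            ([[0.5, 0.5]], [0], np.log(2)),
            ([np.full(10, 0.1)], [3], np.log(10)),
        ],
    )
    def test_nll_examples(self, probs, labels, expected):
        assert st.nll_loss(np.array(probs), np.array(labels)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_nll_label_out_of_range(self):
        with pytest.raises(IndexError):
            st.nll_loss(np.array([[0.5, 0.5]]), np.array([2]))

    def test_nll_clamps_zero_probability(self):
        loss = st.nll_loss(np.array([[1.0, 0.0]]), np.array([1]))
        assert np.isfinite(loss)


class TestGradients:
    @pytest.mark.parametrize("task, sizes", [
        ("classification", [4, 5, 3]),
        ("classification", [3, 4, 4, 2]),
        ("regression", [4, 6, 1]),
        ("regression", [5, 3, 3, 1]),
    ])
    def test_analytic_matches_central_differences(self, task, sizes):
        """Backprop gradients agree with finite differences to 1e-5 relative."""
        rng = np.random.default_rng(abs(hash((task, tuple(sizes)))) % 2**31)
        model = st.init_mlp(sizes, task=task, seed=3)
        x = rng.random((7, sizes[0]))
        if task == "classification":
            targets = rng.integers(0, sizes[-1], size=7)
        else:
            targets = rng.normal(size=7)
        _, gw, gb = _loss_and_grads(model, x, targets)
        eps = 1e-6
        for params, grads in ((model.layer_weights, gw), (model.layer_biases, gb)):
            for p, g in zip(params, grads):
                flat = p.ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp, *_ = _loss_and_grads(model, x, targets)
                    flat[idx] = orig - eps
                    lm, *_ = _loss_and_grads(model, x, targets)
                    flat[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(
                        numeric, rel=1e-5, abs=1e-7
                    )


class TestSGDTrain:
    def settings(self, **kw):
        base = dict(learning_rate=0.2, epochs=5, batch_size=32, seed=0)
        base.update(kw)
        return st.TrainSettings(**base)

    def test_zero_epochs_returns_model_unchanged(self, separable_dataset):
        model = tiny_model([8, 6, 2])
        out, history = st.sgd_train(
            model, separable_dataset.features, separable_dataset.targets,
            self.settings(epochs=0),
        )
        for w0, w1 in zip(model.layer_weights, out.layer_weights):
            assert np.array_equal(w0, w1)
        assert history.per_epoch_loss == []

    def test_tiny_learning_rate_leaves_weights_almost_fixed(self, separable_dataset):
        model = tiny_model([8, 6, 2])
        out, _ = st.sgd_train(
            model, separable_dataset.features, separable_dataset.targets,
            self.settings(learning_rate=1e-12, epochs=2),
        )
        for w0, w1 in zip(model.layer_weights, out.layer_weights):
            assert np.allclose(w0, w1, atol=1e-9)

    def test_loss_decreases_on_separable_data(self, separable_dataset):
        model = tiny_model([8, 8, 2])
        _, history = st.sgd_train(
            model, separable_dataset.features, separable_dataset.targets,
            self.settings(learning_rate=0.1, epochs=20, batch_size=50),
        )
        assert len(history.per_epoch_loss) == 20
        assert history.final_loss < history.per_epoch_loss[0]

    def test_seed_determinism_bitwise(self, separable_dataset):
        runs = []
        for _ in range(2):
            model = tiny_model([8, 6, 2])
            _, history = st.sgd_train(
                model, separable_dataset.features, separable_dataset.targets,
                self.settings(dropout_rate=0.3, momentum=0.5),
            )
            runs.append(history.per_epoch_loss)
        assert runs[0] == runs[1]

    def test_dropout_zero_equals_plain_trainer(self, separable_dataset):
        losses = []
        for dropout in (0.0, 0.0):
            model = tiny_model([8, 6, 2])
            _, history = st.sgd_train(
                model, separable_dataset.features, separable_dataset.targets,
                self.settings(dropout_rate=dropout),
            )
            losses.append(history.per_epoch_loss)
        assert losses[0] == losses[1]

    def test_training_improves_accuracy_most_seeds(self, separable_dataset):
        wins = 0
        for seed in range(10):
            model = st.init_mlp([8, 8, 2], seed=seed)
            _, before = st.predict(model, separable_dataset.features)
            trained, _ = st.sgd_train(
                model, separable_dataset.features, separable_dataset.targets,
                self.settings(learning_rate=0.2, epochs=15, seed=seed),
            )
            _, after = st.predict(trained, separable_dataset.features)
            y = separable_dataset.targets
            wins += np.mean(after == y) > np.mean(before == y)
        assert wins >= 9

    def test_divergence_is_flagged_not_swallowed(self):
        # exploding regression targets with a huge step guarantee overflow
        rng = np.random.default_rng(0)
        x = rng.random((64, 4))
        y = 1e6 * rng.normal(size=64)
        model = st.init_mlp([4, 4, 1], task="regression", seed=0)
        _, history = st.sgd_train(
            model, x, y,
            st.TrainSettings(learning_rate=1e6, epochs=10, batch_size=16, seed=0),
        )
        assert history.diverged
        assert history.per_epoch_loss[-1] == np.inf

    def test_regression_fits_linear_map(self):
        rng = np.random.default_rng(1)
        x = rng.random((128, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 0.3
        model = st.init_mlp([3, 8, 1], task="regression", seed=1)
        trained, history = st.sgd_train(
            model, x, y,
            st.TrainSettings(learning_rate=0.3, epochs=60, batch_size=32, seed=1),
        )
        assert history.final_loss < 0.05


class TestPredict:
    def test_argmax_labels(self):
        model = st.init_mlp([2, 3], seed=0)
        raw, labels = st.predict(model, np.array([[0.2, 0.8]]))
        assert labels[0] == raw[0].argmax()
        assert raw.shape == (1, 3)

    def test_prediction_is_deterministic(self, separable_dataset, rng):
        model = st.init_mlp([8, 5, 2], seed=2)
        a = st.predict(model, separable_dataset.features)
        b = st.predict(model, separable_dataset.features)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_linear_model_matches_affine_map(self):
        w = np.array([[1.0], [2.0], [-1.0]])
        b = np.array([0.5])
        model = st.MLPModel([w], [b], output_activation="linear", task="regression")
        x = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 0.0]])
        raw, values = st.predict(model, x)
        assert np.allclose(values, x @ w.ravel() + 0.5)

    def test_width_mismatch_raises(self):
        model = st.init_mlp([4, 2], seed=0)
        with pytest.raises(ShapeError):
            st.predict(model, np.ones((3, 5)))


class TestModelStructure:
    def test_shape_chain_enforced(self):
        with pytest.raises(ShapeError):
            st.MLPModel(
                [np.ones((3, 4)), np.ones((5, 2))],
                [np.zeros(4), np.zeros(2)],
            )

    def test_regression_output_width_one(self):
        with pytest.raises(ShapeError):
            st.MLPModel([np.ones((3, 2))], [np.zeros(2)], task="regression")

    def test_serialization_roundtrip_bit_exact(self, tmp_path):
        model = st.init_mlp([5, 7, 3], seed=9)
        ts = st.TrainSettings(learning_rate=0.123, momentum=0.4, epochs=3)
        path = tmp_path / "model.json"
        st.save_model(model, path, ts)
        loaded, loaded_ts = st.load_model(path)
        for a, b in zip(model.layer_weights, loaded.layer_weights):
            assert np.array_equal(a, b)
        for a, b in zip(model.layer_biases, loaded.layer_biases):
            assert np.array_equal(a, b)
        assert loaded.hidden_activation == model.hidden_activation
        assert loaded_ts == ts

    @pytest.mark.parametrize("field, value", [
        ("learning_rate", 0.0),
        ("momentum", 1.0),
        ("decay", -0.1),
        ("dropout_rate", 1.0),
        ("batch_size", 0),
    ])
    def test_train_settings_validation(self, field, value):
        kwargs = dict(learning_rate=0.1)
        kwargs[field] = value
        with pytest.raises(ValueError):
            st.TrainSettings(**kwargs)
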