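import numpy as np
import pytest

from ftirq.cnn1d import (
    CnnModel,
    CnnSpec,
    _forward,
    build,
    param_count,
    predict,
    relu,
    train,
)


def tiny_spec(**kw):
    """A desk-size network for fast unit tests."""
    defaults = dict(
        input_length=40, conv_filters=(4, 3, 2), kernel_size=3, dropout_rate=0.5,
        pool_size=2, dense_units=(6, 4, 1), epochs=5, batch_size=8, seed=0,
        learning_rate=0.01,  # the desk-size net takes few steps per epoch
    )
    defaults.update(kw)
    return CnnSpec(**defaults)


class TestArchitecture:
    def test_default_feature_lengths(self):
        lengths = CnnSpec().feature_lengths()
        assert lengths["conv"] == [1799, 1795, 1791]
        assert lengths["pooled"] == 895
        assert lengths["flatten"] == 14320

    def test_default_parameter_counts_from_weight_shapes(self):
        per_layer, total = param_count(build(CnnSpec()))
        assert per_layer == {
            "conv1": 384, "conv2": 10272, "conv3": 2576,
            "dense1": 916544, "dense2": 2080, "dense3": 33,
        }
        assert total == 931_889

    def test_actual_tensor_shapes_match_arithmetic(self):
        model = build(tiny_spec(dropout_rate=0.0))
        x = np.random.default_rng(0).normal(size=(3, 40, 1)).astype(np.float32)
        out, cache = _forward(model, x, rng=None)
        assert cache["a1"].shape == (3, 38, 4)
        assert cache["a2"].shape == (3, 36, 3)
        assert cache["l3"] == 34
        assert cache["flat"].shape == (3, 17 * 2)
        assert out.shape == (3, 1)

    def test_doubling_filters_doubles_that_convs_count(self):
        base, _ = param_count(build(CnnSpec()))
        doubled, _ = param_count(build(CnnSpec(conv_filters=(128, 32, 16))))
        assert doubled["conv1"] == 2 * base["conv1"]

    def test_smallest_dense_layer(self):
        model = build(CnnSpec())
        per_layer, _ = param_count(model)
        assert per_layer["dense3"] == 32 * 1 + 1 == 33

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build(CnnSpec(input_length=10))

    def test_empty_flatten_rejected(self):
        # 13 survives three kernel-5 convolutions (length 1) but pooling by 2
        # leaves nothing to flatten
        with pytest.raises(ValueError, match="flatten"):
            build(CnnSpec(input_length=13))


class TestRelu:
    def test_values(self):
        assert relu(np.array([-1.0, 0.0, 2.0])).tolist() == [0.0, 0.0, 2.0]


class TestForward:
    def test_matches_brute_force_convolution(self):
        # hand-rolled triple loop as the oracle for one conv layer
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 9, 3)).astype(np.float32)
        W = rng.normal(size=(3, 4, 5)).astype(np.float32)  # (C_in, K, C_out)
        b = rng.normal(size=5).astype(np.float32)
        from ftirq.cnn1d import _conv_forward

        got = _conv_forward(x, W, b)
        expected = np.empty((2, 6, 5), dtype=np.float64)
        for n in range(2):
            for l in range(6):
                for o in range(5):
                    acc = b[o]
                    for j in range(4):
                        for c in range(3):
                            acc += x[n, l + j, c] * W[c, j, o]
                    expected[n, l, o] = acc
        assert np.allclose(got, expected, atol=1e-4)

    def test_zero_weight_model_outputs_bias_only(self):
        model = build(tiny_spec())
        for k in model.weights:
            model.weights[k] = np.zeros_like(model.weights[k])
        model.weights["dense3_b"][:] = 1.25
        pred = predict(model, np.random.default_rng(0).normal(size=(5, 40)))
        assert np.allclose(pred, 1.25)

    def test_prediction_shape_and_grid_check(self):
        model = build(tiny_spec())
        X = np.random.default_rng(1).normal(size=(7, 40))
        assert predict(model, X).shape == (7,)
        with pytest.raises(ValueError, match="input_length|shape"):
            predict(model, X[:, :-1])


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        # float64 copy of a tiny net; central differences as the oracle
        from ftirq.cnn1d import _backward

        model = build(tiny_spec(dropout_rate=0.0, seed=4))
        model.weights = {k: v.astype(np.float64) for k, v in model.weights.items()}
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 40, 1))
        y = rng.normal(size=4)

        def loss():
            out, _ = _forward(model, x, rng=None)
            return float(np.mean((out[:, 0] - y) ** 2))

        out, cache = _forward(model, x, rng=None)
        dout = (2.0 * (out[:, 0] - y) / 4)[:, None]
        grads = _backward(model, x, dout, cache)

        eps = 1e-6
        for name in ("conv1_W", "conv2_W", "conv3_W", "dense1_W", "dense3_b"):
            W = model.weights[name]
            flat_idx = [0, W.size // 2, W.size - 1]
            for i in flat_idx:
                orig = W.flat[i]
                W.flat[i] = orig + eps
                up = loss()
                W.flat[i] = orig - eps
                down = loss()
                W.flat[i] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].flat[i] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_constant_labels_converge_to_constant_predictor(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(32, 40)).astype(np.float32)
        y = np.full(32, 2.0)
        model = build(tiny_spec(epochs=60, dropout_rate=0.0, seed=7))
        train(model, X, y)
        assert model.training_history[-1]["train_loss"] < 0.01
        assert np.allclose(predict(model, X), 2.0, atol=0.3)

    def test_same_seed_reproduces_training_exactly(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 40)).astype(np.float32)
        y = rng.uniform(0, 4, 24).astype(np.float32)
        runs = []
        for _ in range(2):
            model = build(tiny_spec(epochs=4, seed=9))
            train(model, X, y)
            runs.append(model.training_history[-1]["train_loss"])
        assert runs[0] == runs[1]

    def test_learns_linear_response_on_toy_spectra(self):
        # toy mixture: one band grows with y; network should fit it quickly
        rng = np.random.default_rng(10)
        t = np.linspace(0, 1, 40)
        band = np.exp(-0.5 * ((t - 0.5) / 0.08) ** 2)
        y = rng.uniform(0, 4, 300)
        X = np.outer(y, band) + rng.normal(0, 0.02, size=(300, 40))
        model = build(tiny_spec(epochs=120, dropout_rate=0.0, seed=11))
        train(model, X[:240], y[:240], X[240:], y[240:])
        pred = predict(model, X[240:])
        ss_res = np.sum((y[240:] - pred) ** 2)
        ss_tot = np.sum((y[240:] - y[240:].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9

    def test_history_records_every_epoch(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(16, 40)).astype(np.float32)
        y = rng.uniform(0, 1, 16)
        model = build(tiny_spec(epochs=3))
        train(model, X, y, X, y)
        assert [h["epoch"] for h in model.training_history] == [1, 2, 3]
        assert all("val_loss" in h for h in model.training_history)

    def test_mismatched_sample_counts_rejected(self):
        model = build(tiny_spec())
        with pytest.raises(ValueError, match="differ"):
            train(model, np.zeros((4, 40)), np.zeros(3))
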