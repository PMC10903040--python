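import numpy as np
import pytest

from hormonet import nets, synthgen
from hormonet.nets import builders, layers as L
from hormonet.nets.training import Model, TrainConfig

from oracles import conv1d_oracle


# ------------------------------------------------------------- activations

def test_relu_cases():
    assert L.relu(-3) == 0 and L.relu(2) == 2
    assert np.array_equal(L.relu(np.array([-1.0, 0.0, 1.5])), [0.0, 0.0, 1.5])


def test_sigmoid_properties():
    assert L.sigmoid(0.0) == 0.5
    xs = np.linspace(-10, 10, 101)
    ys = L.sigmoid(xs)
    assert np.all(np.diff(ys) > 0) and np.all((ys > 0) & (ys < 1))
    assert np.isclose(L.sigmoid(np.array([500.0]))[0], 1.0)  # no overflow


def test_softmax_simplex():
    assert np.allclose(L.softmax(np.zeros(3)), [1 / 3] * 3)
    z = np.random.default_rng(0).normal(size=(5, 4)) * 50
    p = L.softmax(z)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.all(p >= 0)


# ------------------------------------------------------------- convolution

def test_conv1d_valid_identity_and_hand_sum():
    assert np.allclose(L.conv1d_valid(np.array([3.0, -1.0, 2.0]), np.array([1.0])), [3, -1, 2])
    out = L.conv1d_valid(np.array([1.0, 2, 3, 4]), np.array([1.0, 1.0]))
    assert np.allclose(out, [3, 5, 7])


def test_conv1d_valid_matches_double_loop_oracle(rng):
    for _ in range(5):
        sig = rng.normal(size=rng.integers(5, 30))
        ker = rng.normal(size=rng.integers(1, len(sig) + 1))
        bias = float(rng.normal())
        assert np.allclose(
            L.conv1d_valid(sig, ker, bias),
            conv1d_oracle(list(sig), list(ker), bias),
            atol=1e-12,
        )


def test_conv1d_kernel_too_long():
    with pytest.raises(ValueError, match="kernel"):
        L.conv1d_valid(np.zeros(3), np.zeros(5))


# ------------------------------------------------------------------ losses

def test_cce_perfect_prediction_is_zero():
    onehot = np.eye(3)
    assert L.cce_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-9)


def test_bce_at_half_is_ln2():
    y = np.array([0, 1, 0, 1])
    assert L.bce_loss(np.full(4, 0.5), y) == pytest.approx(np.log(2))


# --------------------------------------------------------- gradient checks

def _numeric_grad(f, param, eps=1e-6):
    grad = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = param[idx]
        param[idx] = orig + eps
        hi = f()
        param[idx] = orig - eps
        lo = f()
        param[idx] = orig
        grad[idx] = (hi - lo) / (2 * eps)
    return grad


@pytest.mark.parametrize("head,n_classes", [("sigmoid", 1), ("softmax", 3)])
def test_backprop_matches_numeric_gradients(head, n_classes):
    """End-to-end gradient check through conv, batchnorm, pool, GAP,
    dense and both loss heads on a tiny network."""
    rng = np.random.default_rng(0)
    spec = builders.ArchitectureSpec(
        input_length=12,
        layers=(
            builders.LayerSpec("conv", {"filters": 3, "kernel": 3, "activation": "relu"}),
            builders.LayerSpec("batchnorm"),
            builders.LayerSpec("maxpool", {"window": 2, "stride": 2}),
            builders.LayerSpec("global_average_pool"),
            builders.LayerSpec("dense", {"units": 4, "activation": "relu"}),
            builders.LayerSpec(
                "output",
                {"head": head} if head == "sigmoid" else {"head": head, "n_classes": n_classes},
            ),
        ),
    )
    model = Model(spec, seed=1)
    x = rng.normal(size=(6, 12, 1))
    y = rng.integers(0, max(n_classes, 2), size=6)

    def loss_fn():
        out = x
        for layer in model.layers:
            out = layer.forward(out, training=True)
        return model._loss_and_headgrad(out, y)[0]

    # analytic pass (batchnorm uses batch stats in both passes)
    out = x
    for layer in model.layers:
        out = layer.forward(out, training=True)
    loss, grad = model._loss_and_headgrad(out, y)
    for layer in reversed(model.layers):
        grad = layer.backward(grad)
    for layer in model.layers:
        for p, g in zip(layer.params, layer.grads):
            num = _numeric_grad(loss_fn, p)
            assert np.allclose(g, num, atol=1e-5), type(layer).__name__


def test_lstm_gradients_numeric():
    rng = np.random.default_rng(3)
    lstm = L.LSTMLayer(2, 3, rng)
    dense = L.Dense(3, 1, rng)
    x = rng.normal(size=(4, 5, 2))
    y = rng.integers(0, 2, size=4).astype(float)

    def loss_fn():
        h = lstm.forward(x, training=True)
        z = dense.forward(h, training=True)
        p = L.sigmoid(z[:, 0])
        return L.bce_loss(p, y)

    h = lstm.forward(x, training=True)
    z = dense.forward(h, training=True)
    p = L.sigmoid(z[:, 0])
    grad = ((p - y) / len(y))[:, None]
    lstm.backward(dense.backward(grad))
    num_w = _numeric_grad(loss_fn, lstm.w)
    assert np.allclose(lstm.grads[0], num_w, atol=1e-5)


# ---------------------------------------------------------------- builders

def test_hdi_spec_shapes_positive():
    spec = nets.build_hdi_model(100)
    shapes = spec.shapes()
    assert all(all(d > 0 for d in shape) for _, shape in shapes)
    assert shapes[-1][1] == (1,)


def test_risk_spec_has_batchnorm_and_softmax():
    spec = nets.build_risk_model(100)
    kinds = [l.kind for l in spec.layers]
    assert kinds.count("batchnorm") == 2
    assert kinds.count("dense") == 5
    assert spec.head == "softmax" and spec.n_classes == 3


def test_paper_dims_input_builds():
    spec = nets.build_hdi_model(900)
    assert all(all(d > 0 for d in s) for _, s in spec.shapes())


def test_input_too_short_names_layer():
    with pytest.raises(builders.ShapeError, match="conv|maxpool"):
        nets.build_hdi_model(8)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="adam")


# ---------------------------------------------------------------- training

def test_mlp_overfits_separable_toy():
    X, y = synthgen.gen_feature_table(20, 30, 2, class_sep=4.0, seed=1)
    spec = nets.build_mlp(30)
    _, hist = nets.train(spec, X, y, TrainConfig(epochs=50, learning_rate=0.005, batch_size=4, seed=0))
    assert hist[-1]["accuracy"] == 1.0
    assert len(hist) == 50


def test_lstm_accepts_sequence_shape_and_learns():
    X, y = synthgen.gen_feature_table(20, 15, 2, class_sep=4.0, seed=2)
    spec = nets.build_lstm(15, units=16)
    model, hist = nets.train(spec, X, y, TrainConfig(epochs=40, learning_rate=0.01, batch_size=4, seed=0))
    assert hist[-1]["loss"] < hist[0]["loss"]
    assert hist[-1]["accuracy"] == 1.0
    p = model.predict_proba(X)
    assert np.all((p >= 0) & (p <= 1))


def test_risk_cnn_softmax_output_and_decreasing_loss():
    X, y = synthgen.gen_feature_table(18, 40, 3, class_sep=4.0, seed=3)
    spec = nets.build_risk_model(40)
    model, hist = nets.train(spec, X, y, TrainConfig(epochs=8, learning_rate=0.002, batch_size=6, seed=0))
    assert hist[-1]["loss"] < hist[0]["loss"]
    p = model.predict_proba(X)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_training_reproducible_under_seed():
    X, y = synthgen.gen_feature_table(16, 20, 2, class_sep=2.0, seed=4)
    spec = nets.build_mlp(20)
    cfg = TrainConfig(epochs=5, learning_rate=0.005, batch_size=4, seed=9)
    _, h1 = nets.train(spec, X, y, cfg)
    _, h2 = nets.train(spec, X, y, cfg)
    assert h1 == h2
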