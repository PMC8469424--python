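import numpy as np
import pytest

from ecgnets import nn


def _check_grads(layer, x, training=True, rel=1e-6, abs_tol=1e-8, check_input=True):
    """Central-difference check of input and parameter gradients under the
    linear functional loss = sum(forward(x) * w)."""
    rng = np.random.default_rng(99)
    w = rng.normal(size=layer.forward(x, training=training).shape)

    def loss():
        return float((layer.forward(x, training=training) * w).sum())

    for p in layer.params():
        p.zero_grad()
    layer.forward(x, training=training)
    gin = layer.backward(w)
    eps = 1e-6

    if check_input:
        flat = x.reshape(-1)
        gflat = gin.reshape(-1)
        idx = rng.choice(flat.size, size=min(25, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            up = loss()
            flat[i] = orig - eps
            dn = loss()
            flat[i] = orig
            assert gflat[i] == pytest.approx((up - dn) / (2 * eps),
                                             rel=rel, abs=abs_tol)
    for p in layer.params():
        pf = p.value.reshape(-1)
        gf = p.grad.reshape(-1)
        idx = rng.choice(pf.size, size=min(25, pf.size), replace=False)
        for i in idx:
            orig = pf[i]
            pf[i] = orig + eps
            up = loss()
            pf[i] = orig - eps
            dn = loss()
            pf[i] = orig
            assert gf[i] == pytest.approx((up - dn) / (2 * eps),
                                          rel=rel, abs=abs_tol)


def test_dense_gradients(rng):
    layer = nn.Dense(7, 4, rng)
    _check_grads(layer, rng.normal(size=(5, 7)))


def test_conv1d_gradients_stride_padding(rng):
    layer = nn.Conv1d(3, 4, 5, rng, stride=2, padding=2)
    _check_grads(layer, rng.normal(size=(2, 3, 17)))


def test_conv1d_output_length():
    assert nn.Conv1d.out_length(1000, 5, 2, 2) == 500
    assert nn.Conv1d.out_length(17, 5, 2, 2) == 9


def test_layernorm_gradients(rng):
    layer = nn.LayerNorm(4)
    _check_grads(layer, rng.normal(size=(3, 4, 11)), rel=1e-4, abs_tol=1e-6)


def test_batchnorm_gradients_and_running_stats(rng):
    layer = nn.BatchNorm1d(6)
    x = rng.normal(2.0, 3.0, size=(32, 6))
    _check_grads(layer, x.copy(), training=True, rel=1e-4, abs_tol=1e-6)
    for _ in range(200):
        layer.forward(rng.normal(2.0, 3.0, size=(32, 6)), training=True)
    out = layer.forward(rng.normal(2.0, 3.0, size=(64, 6)), training=False)
    # eval mode uses running stats: output roughly standardized
    assert abs(out.mean()) < 0.3
    assert 0.7 < out.std() < 1.3


def test_avgpool_gradients_and_ceil_mode(rng):
    layer = nn.AvgPool1d(2)
    x = rng.normal(size=(2, 3, 7))  # odd length exercises the ceil-mode tail
    out = layer.forward(x)
    assert out.shape == (2, 3, 4)
    _check_grads(layer, x)


def test_adaptive_avgpool_gradients_and_mean_preservation(rng):
    layer = nn.AdaptiveAvgPool1d(16)
    # evenly divisible length: pooling preserves the global mean exactly
    x = rng.normal(size=(2, 3, 256))
    out = layer.forward(x)
    assert out.shape == (2, 3, 16)
    np.testing.assert_allclose(out.mean(), x.mean(), atol=1e-12)
    # uneven length: bins overlap/differ in width, check only shape and grads
    x2 = rng.normal(size=(2, 3, 250))
    assert layer.forward(x2).shape == (2, 3, 16)
    _check_grads(layer, x2)


def test_softmax_rows_and_gradients(rng):
    layer = nn.Softmax()
    x = rng.normal(size=(6, 5))
    out = layer.forward(x)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
    assert (out > 0).all()
    _check_grads(layer, x)


def test_leaky_relu(rng):
    layer = nn.LeakyReLU(0.01)
    x = np.array([[-2.0, 3.0]])
    np.testing.assert_allclose(layer.forward(x), [[-0.02, 3.0]])
    _check_grads(layer, rng.normal(size=(4, 9)) + 0.1)  # keep away from the kink


def test_dropout_eval_identity_and_train_expectation(rng):
    layer = nn.Dropout(0.4, rng)
    x = np.ones((2000, 10))
    np.testing.assert_array_equal(layer.forward(x, training=False), x)
    out = layer.forward(x, training=True)
    kept = out != 0
    # inverted dropout: surviving activations scaled by 1/(1-p)
    np.testing.assert_allclose(out[kept], 1.0 / 0.6)
    assert kept.mean() == pytest.approx(0.6, abs=0.02)


def test_flatten_roundtrip(rng):
    layer = nn.Flatten()
    x = rng.normal(size=(4, 3, 5))
    out = layer.forward(x)
    assert out.shape == (4, 15)
    np.testing.assert_array_equal(layer.backward(out), x)


def test_cross_entropy_value_and_gradient(rng):
    probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
    y = np.array([0, 1])
    loss, g = nn.cross_entropy(probs, y)
    assert loss == pytest.approx(-(np.log(0.7) + np.log(0.8)) / 2)
    eps = 1e-7
    for i, j in [(0, 0), (1, 1), (1, 2)]:
        p2 = probs.copy()
        p2[i, j] += eps
        up, _ = nn.cross_entropy(p2, y)
        p2[i, j] -= 2 * eps
        dn, _ = nn.cross_entropy(p2, y)
        assert g[i, j] == pytest.approx((up - dn) / (2 * eps), rel=1e-5)


def test_sequential_composes_and_adam_converges(rng):
    # least squares via a single Dense layer; Adam should fit it closely
    model = nn.Sequential(nn.Dense(3, 1, rng))
    true_w = np.array([[1.5], [-2.0], [0.5]])
    x = rng.normal(size=(256, 3))
    y = x @ true_w + 0.3
    opt = nn.Adam(model.params(), lr=0.05)
    for _ in range(300):
        pred = model.forward(x)
        g = 2 * (pred - y) / len(x)
        opt.zero_grad()
        model.backward(g)
        opt.step()
    mse = float(((model.forward(x) - y) ** 2).mean())
    assert mse < 1e-6
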