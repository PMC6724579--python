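"""Feed-forward network and scaled-conjugate-gradient training."""

import numpy as np
import pytest

from structimm.errors import ConfigError
from structimm.evaluation import roc_auc
from structimm.network import (NetworkModel, NetworkSpec, forward, gradient,
                               loss, scg_train)


def test_zero_weights_score_half():
    m = NetworkModel.initialize(NetworkSpec(4, 3), seed=0)
    m.w1[:] = 0.0
    m.w2[:] = 0.0
    assert forward(m, np.zeros(4)) == pytest.approx(0.5)


def test_hand_computed_forward():
    """2-input, 1-hidden toy evaluated by hand arithmetic."""
    m = NetworkModel.initialize(NetworkSpec(2, 1), seed=0)
    m.w1 = np.array([[0.5, -0.25, 0.1]])   # w_x1, w_x2, bias
    m.w2 = np.array([[2.0, -1.0]])         # w_h, bias
    x = np.array([1.0, 2.0])
    h = np.tanh(0.5 * 1.0 - 0.25 * 2.0 + 0.1)
    expected = 1.0 / (1.0 + np.exp(-(2.0 * h - 1.0)))
    assert forward(m, x) == pytest.approx(expected, abs=1e-12)


def test_monotone_in_positive_path():
    m = NetworkModel.initialize(NetworkSpec(1, 1), seed=0)
    m.w1 = np.array([[1.0, 0.0]])
    m.w2 = np.array([[1.0, 0.0]])
    scores = [forward(m, np.array([v])) for v in (-2.0, -1.0, 0.0, 1.0, 2.0)]
    assert np.all(np.diff(scores) > 0)
    assert all(0 < s < 1 for s in scores)


def test_dimension_mismatch_message():
    m = NetworkModel.initialize(NetworkSpec(5, 2), seed=0)
    with pytest.raises(ConfigError, match="5"):
        forward(m, np.zeros(4))


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    m = NetworkModel.initialize(NetworkSpec(4, 3), seed=1)
    x = rng.normal(size=(20, 4))
    y = (rng.uniform(size=20) < 0.5).astype(float)
    g = gradient(m, x, y)
    w0 = m.get_params()
    eps = 1e-6
    for i in range(len(w0)):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        m.set_params(wp)
        lp = loss(m, x, y)
        m.set_params(wm)
        lm = loss(m, x, y)
        fd = (lp - lm) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)
    m.set_params(w0)


def test_batch_gradient_is_mean_of_examples():
    rng = np.random.default_rng(2)
    m = NetworkModel.initialize(NetworkSpec(3, 2), seed=3)
    x = rng.normal(size=(6, 3))
    y = np.array([0, 1, 0, 1, 1, 0], float)
    g_batch = gradient(m, x, y)
    g_each = np.mean([gradient(m, x[i:i + 1], y[i:i + 1])
                      for i in range(6)], axis=0)
    assert np.allclose(g_batch, g_each, atol=1e-12)


def test_gradient_rejects_bad_input():
    m = NetworkModel.initialize(NetworkSpec(2, 1), seed=0)
    with pytest.raises(ValueError):
        gradient(m, np.array([[np.nan, 0.0]]), np.array([1.0]))
    with pytest.raises(ConfigError):
        gradient(m, np.zeros((0, 2)), np.zeros(0))


def test_scg_solves_separable_toy():
    rng = np.random.default_rng(4)
    x = np.vstack([rng.normal(-2, 0.5, size=(100, 2)),
                   rng.normal(2, 0.5, size=(100, 2))])
    y = np.array([0] * 100 + [1] * 100)
    m = NetworkModel.initialize(NetworkSpec(2, 3), seed=0)
    m = scg_train(m, x, y, x, y, max_epochs=300)
    assert roc_auc(forward(m, x), y) == 1.0


def test_scg_deterministic():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(60, 3))
    y = (x[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
    runs = []
    for _ in range(2):
        m = NetworkModel.initialize(NetworkSpec(3, 2), seed=7)
        m = scg_train(m, x[:40], y[:40], x[40:], y[40:], max_epochs=100)
        runs.append(np.concatenate([m.w1.ravel(), m.w2.ravel()]))
    assert np.array_equal(runs[0], runs[1])


def test_early_stopping_returns_best_validation_snapshot():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(80, 4))
    y = (x[:, 0] > 0).astype(int)
    m = NetworkModel.initialize(NetworkSpec(4, 4), seed=1)
    xt, yt, xv, yv = x[:50], y[:50], x[50:], y[50:]
    m = scg_train(m, xt, yt, xv, yv, max_epochs=200, patience=4)
    # re-evaluating the returned snapshot must give the minimum val loss
    xvs = (xv - m.mu) / m.sigma
    final_val = loss(m, xvs, yv.astype(float))
    # retrain with huge patience: best val loss can only improve or match
    m2 = NetworkModel.initialize(NetworkSpec(4, 4), seed=1)
    m2 = scg_train(m2, xt, yt, xv, yv, max_epochs=200, patience=10 ** 6)
    xvs2 = (xv - m2.mu) / m2.sigma
    assert loss(m2, xvs2, yv.astype(float)) <= final_val + 1e-9


def test_standardization_from_training_only():
    rng = np.random.default_rng(8)
    x_train = rng.normal(loc=5.0, scale=3.0, size=(50, 2))
    x_val = rng.normal(loc=-5.0, scale=1.0, size=(10, 2))
    y_train = (x_train[:, 0] > 5).astype(int)
    y_val = (x_val[:, 0] > -5).astype(int)
    m = NetworkModel.initialize(NetworkSpec(2, 2), seed=0)
    m = scg_train(m, x_train, y_train, x_val, y_val, max_epochs=10)
    assert np.allclose(m.mu, x_train.mean(axis=0))
    assert np.allclose(m.sigma, x_train.std(axis=0))
    xs = (x_train - m.mu) / m.sigma
    assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(xs.std(axis=0), 1.0, atol=1e-12)


def test_serialization_bit_exact_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    m = NetworkModel.initialize(NetworkSpec(6, 3), seed=2)
    m.mu = rng.normal(size=6)
    m.sigma = np.abs(rng.normal(size=6)) + 0.5
    p = tmp_path / "model.json"
    m.save(p)
    m2 = NetworkModel.load(p)
    assert np.array_equal(m.w1, m2.w1)
    assert np.array_equal(m.w2, m2.w2)
    assert np.array_equal(m.mu, m2.mu)
    assert np.array_equal(m.sigma, m2.sigma)
    x = rng.normal(size=6)
    assert forward(m, x) == forward(m2, x)


def test_constant_feature_gets_unit_scale():
    x = np.ones((10, 2))
    x[:, 1] = np.arange(10)
    m = NetworkModel.initialize(NetworkSpec(2, 1), seed=0)
    m.set_standardization(x)
    assert m.sigma[0] == 1.0  # zero-variance guard
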