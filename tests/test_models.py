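"""Forward-pass fixtures against hand arithmetic, the cross-layer residual
contract, finite-difference gradient checks, and training behaviour."""

import copy

import numpy as np
import pytest
from sklearn.base import clone

from epicrossnet.exceptions import ParameterError, TrainingError
from epicrossnet.models import (
    CrossNetClassifier,
    SequenceConvClassifier,
    _cnn_forward_backward,
    _dcn_forward_backward,
    bce_loss,
    cross_forward,
    deep_forward,
    embed,
    forward_logit,
    init_dcn_params,
    predict_proba_fn,
    sigmoid,
)


def toy_params():
    """Fixed-weight 2-d toy network used by the hand-computed fixtures."""
    I = np.eye(2)
    return {
        "n_deep_layers": 2,
        "W_embed": I.copy(), "b_embed": np.zeros(2),
        "W_deep_0": np.array([[1.0, -1.0], [1.0, 1.0]]), "b_deep_0": np.zeros(2),
        "W_deep_1": np.array([[1.0], [1.0]]), "b_deep_1": np.array([0.5]),
        "W_cross": I.copy(), "b_cross": np.zeros(2),
        "W_proj": np.array([[1.0], [1.0]]), "b_proj": np.zeros(1),
    }


def test_embed_identity_and_zero():
    p = toy_params()
    x = np.array([[1.0, 2.0]])
    assert np.allclose(embed(p, x), x)
    assert np.allclose(embed(p, np.zeros((1, 2))), p["b_embed"])


def test_embed_random_case_vs_hand_matmul():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(3, 2))
    b = rng.normal(size=2)
    x = rng.normal(size=3)
    expected = [sum(x[i] * W[i, j] for i in range(3)) + b[j] for j in range(2)]
    out = embed({"W_embed": W, "b_embed": b}, x)
    assert np.allclose(out, [expected], atol=1e-10)


def test_deep_forward_hand_fixture():
    p = toy_params()
    # x=[1,2]: z0=[3,1] -> relu -> 3+1+0.5 = 4.5
    assert deep_forward(p, np.array([[1.0, 2.0]])) == pytest.approx([4.5])
    # all-negative pre-activations: x=[-1,-1] -> z0=[-2,0] -> relu [0,0] -> 0.5
    assert deep_forward(p, np.array([[-1.0, -1.0]])) == pytest.approx([0.5])


def test_deep_single_identity_layer():
    p = {"n_deep_layers": 1, "W_deep_0": np.array([[1.0]]),
         "b_deep_0": np.zeros(1)}
    assert deep_forward(p, np.array([[3.5]])) == pytest.approx([3.5])


def test_cross_layer_hand_fixture():
    """x=[1,2], W=I, b=0 -> [1*1+1, 2*2+2] = [2, 6]."""
    p = toy_params()
    out = cross_forward(p, np.array([[1.0, 2.0]]))
    assert np.allclose(out, [[2.0, 6.0]], atol=1e-10)


def test_cross_layer_residual_contract():
    """With zero weights the cross layer is the identity on its input."""
    rng = np.random.default_rng(1)
    E = rng.normal(size=(5, 8))
    p = {"W_cross": np.zeros((8, 8)), "b_cross": np.zeros(8)}
    assert np.allclose(cross_forward(p, E), E, atol=1e-12)
    # and with zero input it returns the bias
    p["b_cross"] = rng.normal(size=8)
    assert np.allclose(cross_forward(p, np.zeros((1, 8))), p["b_cross"][None])


def test_end_to_end_forward_composition():
    """predict equals the hand composition of embed/deep/cross/projection."""
    p = toy_params()
    x = np.array([[1.0, 2.0]])
    # deep = 4.5; cross = [2,6]; proj = 8; logit = 12.5
    assert forward_logit(p, x) == pytest.approx([12.5], abs=1e-10)
    assert predict_proba_fn(p, x) == pytest.approx([sigmoid(np.array([12.5]))[0]])
    E = embed(p, x)
    manual = deep_forward(p, E) + (cross_forward(p, E) @ p["W_proj"])[:, 0]
    assert np.allclose(forward_logit(p, x), manual, atol=1e-12)


def test_sigmoid_midpoint_and_limits():
    assert sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)
    z = np.linspace(-30, 30, 11)
    p = sigmoid(z)
    assert (np.diff(p) > 0).all()
    assert p[-1] == pytest.approx(1.0, abs=1e-10)


def test_bce_loss_values():
    assert bce_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(
        -np.log(1 - 1e-7), abs=1e-9)
    assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(
        np.log(2), abs=1e-12)
    big = bce_loss(np.array([0.0]), np.array([1.0]))
    assert np.isfinite(big) and big == pytest.approx(-np.log(1e-7), rel=1e-6)


def _finite_diff_check(params, forward_backward, X, y, keys, rel_tol=1e-4):
    _, grads = forward_backward(params, X, y)
    h = 1e-5
    worst = 0.0
    for key in keys:
        arr = params[key]
        flat = arr.ravel()
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + h
            lp, _ = forward_backward(params, X, y)
            flat[idx] = orig - h
            lm, _ = forward_backward(params, X, y)
            flat[idx] = orig
            num = (lp - lm) / (2 * h)
            ana = grads[key].ravel()[idx]
            denom = max(abs(num), abs(ana), 1e-8)
            worst = max(worst, abs(num - ana) / denom)
    assert worst < rel_tol, f"max relative gradient error {worst}"


def test_dcn_gradients_match_finite_differences():
    """Analytic backprop vs central differences on a 24-parameter model."""
    rng = np.random.default_rng(3)
    params = init_dcn_params(2, 2, (2, 1), rng)
    X = rng.normal(size=(6, 2))
    y = np.array([0, 1, 1, 0, 1, 0], dtype=float)
    keys = [k for k in params if k.startswith(("W_", "b_"))]
    _finite_diff_check(params, _dcn_forward_backward, X, y, keys)


def test_cnn_gradients_match_finite_differences():
    rng = np.random.default_rng(4)
    k, c1, c2 = 3, 2, 3
    def layer(fan_in, shape):
        lim = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-lim, lim, size=shape)
    params = {
        "kernel_size": k,
        "W_conv1": layer(k * 4, (k * 4, c1)), "b_conv1": layer(k * 4, (c1,)),
        "W_conv2": layer(k * c1, (k * c1, c2)), "b_conv2": layer(k * c1, (c2,)),
        "W_out": layer(c2, (c2, 1)), "b_out": layer(c2, (1,)),
    }
    X = rng.random((5, 12, 4))
    y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
    keys = [k for k in params if k != "kernel_size"]
    _finite_diff_check(params, _cnn_forward_backward, X, y, keys)


def _separable_data(n=300, d=8, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, d)) + 2.0 * y[:, None]
    return X, y


def test_training_reduces_loss_and_is_deterministic():
    X, y = _separable_data()
    clf = CrossNetClassifier(embedding_dim=16, hidden_dims=(8, 1), epochs=15,
                             random_state=5)
    clf.fit(X, y)
    hist = clf.history_
    assert hist["train_loss"][-1] < hist["train_loss"][0]
    assert clf.best_epoch_ == int(np.argmin(hist["val_loss"]))
    clf2 = clone(clf).fit(X, y)
    assert hist["train_loss"] == clf2.history_["train_loss"]
    assert all(np.array_equal(clf.params_[k], clf2.params_[k])
               for k in clf.params_ if k != "n_deep_layers")
    assert clf.score(X, y) > 0.9


def test_best_val_checkpoint_differs_from_last():
    X, y = _separable_data(seed=2)
    best = CrossNetClassifier(embedding_dim=8, hidden_dims=(4, 1), epochs=6,
                              checkpoint="best_val", random_state=1).fit(X, y)
    last = CrossNetClassifier(embedding_dim=8, hidden_dims=(4, 1), epochs=6,
                              checkpoint="last", random_state=1).fit(X, y)
    assert best.history_["val_loss"] == last.history_["val_loss"]
    assert best.history_["val_loss"][best.best_epoch_] == min(
        best.history_["val_loss"])
    assert last.best_epoch_ == 5


def test_single_class_training_rejected():
    X = np.zeros((20, 4))
    with pytest.raises(TrainingError):
        CrossNetClassifier().fit(X, np.zeros(20))


def test_predict_proba_contract():
    X, y = _separable_data(n=100)
    clf = CrossNetClassifier(embedding_dim=8, hidden_dims=(4, 1), epochs=2,
                             random_state=0).fit(X, y)
    proba = clf.predict_proba(X)
    assert proba.shape == (100, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert ((proba > 0) & (proba < 1)).all()
    with pytest.raises(ParameterError):
        clf.predict_proba(np.zeros((3, 99)))


def test_sequence_baseline_learns_planted_motif():
    """Strong planted motif -> high test AUROC; output stays in (0,1)."""
    from epicrossnet.evaluation import auroc

    rng = np.random.default_rng(7)
    n = 400
    y = rng.integers(0, 2, n)
    seqs = rng.integers(0, 4, size=(n, 41))
    seqs[y == 1, 10:18] = [0, 2, 0, 2, 1, 3, 1, 3]  # AGAGCUCU motif
    X = np.eye(4)[seqs]
    clf = SequenceConvClassifier(epochs=10, random_state=0)
    clf.fit(X[:300], y[:300])
    p = clf.predict_proba(X[300:])[:, 1]
    assert ((p > 0) & (p < 1)).all()
    assert auroc(p, y[300:]) > 0.8


def test_sklearn_params_roundtrip():
    clf = CrossNetClassifier(epochs=3, embedding_dim=32)
    got = clf.get_params()
    assert got["epochs"] == 3 and got["embedding_dim"] == 32
    clf.set_params(epochs=5)
    assert clf.epochs == 5
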