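"""Shapley attribution: exact enumeration properties (efficiency, null
player, symmetry), sampled-estimator convergence, rankings, beeswarm."""

import numpy as np
import pytest

from epicrossnet.exceptions import ParameterError
from epicrossnet.interpret import (
    BackgroundSet,
    background_value,
    exact_shapley,
    export_beeswarm_table,
    rank_features,
    sampled_shapley,
    sampled_shapley_matrix,
)
from epicrossnet.models import init_dcn_params, predict_proba_fn


def test_additive_model_recovers_coefficients():
    """f(x) = 2 x1 + 3 x2 with zero background -> phi = (2, 3)."""
    fn = lambda Z: 2 * Z[:, 0] + 3 * Z[:, 1]
    bg = BackgroundSet(np.zeros((1, 2)))
    phi = exact_shapley(fn, np.array([1.0, 1.0]), bg)
    assert np.allclose(phi, [2.0, 3.0], atol=1e-12)


def test_two_player_closed_form():
    """Any 2-feature model matches the closed-form two-player Shapley."""
    rng = np.random.default_rng(0)
    W = rng.normal(size=(2, 2))
    fn = lambda Z: np.sin(Z @ W[:, 0]) + (Z @ W[:, 1]) ** 2
    x = rng.normal(size=2)
    bg = BackgroundSet(rng.normal(size=(4, 2)))
    phi = exact_shapley(fn, x, bg)
    def v(mask):
        rows = bg.rows.copy()
        for i, m in enumerate(mask):
            if m:
                rows[:, i] = x[i]
        return float(np.mean(fn(rows)))
    phi0 = 0.5 * (v([1, 0]) - v([0, 0])) + 0.5 * (v([1, 1]) - v([0, 1]))
    phi1 = 0.5 * (v([0, 1]) - v([0, 0])) + 0.5 * (v([1, 1]) - v([1, 0]))
    assert np.allclose(phi, [phi0, phi1], atol=1e-12)


def test_null_player_and_symmetry():
    fn = lambda Z: Z[:, 0] + Z[:, 1]  # ignores feature 2; 0 and 1 symmetric
    bg = BackgroundSet(np.zeros((3, 3)))
    phi = exact_shapley(fn, np.array([2.0, 2.0, 5.0]), bg)
    assert phi[2] == pytest.approx(0.0, abs=1e-12)
    assert phi[0] == pytest.approx(phi[1], abs=1e-12)


def _network_value_fn(F, seed=0, emb=8):
    rng = np.random.default_rng(seed)
    params = init_dcn_params(F, emb, (4, 1), rng)
    return lambda Z: predict_proba_fn(params, np.atleast_2d(Z))


@pytest.mark.parametrize("F", [8, 10])
def test_exact_efficiency_on_fixed_weight_networks(F):
    """Sum of phi equals f(x) - v(empty) to 1e-8."""
    fn = _network_value_fn(F)
    rng = np.random.default_rng(1)
    bg = BackgroundSet(rng.normal(size=(10, F)))
    for _ in range(5):
        x = rng.normal(size=F)
        phi = exact_shapley(fn, x, bg)
        total = float(fn(x[None])[0]) - background_value(fn, bg)
        assert abs(phi.sum() - total) <= 1e-8


def test_sampled_close_to_exact():
    """Permutation sampling at 2000 draws tracks enumeration to < 0.02."""
    F = 10
    fn = _network_value_fn(F, seed=2)
    rng = np.random.default_rng(3)
    bg = BackgroundSet(rng.normal(size=(8, F)))
    x = rng.normal(size=F)
    exact = exact_shapley(fn, x, bg)
    approx = sampled_shapley(fn, x, bg, n_permutations=2000, seed=0)
    assert np.mean(np.abs(approx - exact)) < 0.02
    # efficiency holds for the sampled estimator too (it telescopes exactly)
    total = float(fn(x[None])[0]) - background_value(fn, bg)
    assert abs(approx.sum() - total) <= 0.05


def test_sampled_error_shrinks_with_more_permutations():
    F = 8
    fn = _network_value_fn(F, seed=4)
    rng = np.random.default_rng(5)
    bg = BackgroundSet(rng.normal(size=(5, F)))
    x = rng.normal(size=F)
    exact = exact_shapley(fn, x, bg)
    errs = {}
    for n_perm in (10, 200):
        e = [np.mean(np.abs(sampled_shapley(fn, x, bg, n_perm, seed=s) - exact))
             for s in range(10)]
        errs[n_perm] = np.mean(e)
    assert errs[200] < errs[10]


def test_sampled_determinism_and_guards():
    F = 5
    fn = _network_value_fn(F, seed=6)
    bg = BackgroundSet(np.zeros((2, F)))
    x = np.ones(F)
    a = sampled_shapley(fn, x, bg, n_permutations=1, seed=9)
    b = sampled_shapley(fn, x, bg, n_permutations=1, seed=9)
    assert np.array_equal(a, b)
    with pytest.raises(ParameterError):
        sampled_shapley(fn, x, bg, n_permutations=0)
    with pytest.raises(ParameterError, match="exact-mode guard"):
        exact_shapley(fn, np.ones(20), BackgroundSet(np.zeros((1, 20))))


def test_matrix_estimator_matches_per_sample_statistics():
    """Batched shared-permutation attribution agrees with the per-sample
    estimator in expectation (checked at generous tolerance)."""
    F = 6
    fn = _network_value_fn(F, seed=7)
    rng = np.random.default_rng(8)
    bg = BackgroundSet(rng.normal(size=(4, F)))
    X = rng.normal(size=(3, F))
    phi_mat = sampled_shapley_matrix(fn, X, bg, n_permutations=500, seed=1)
    for i in range(3):
        exact = exact_shapley(fn, X[i], bg)
        assert np.mean(np.abs(phi_mat[i] - exact)) < 0.05


def test_rank_features_ties_and_invariance():
    phi = np.zeros((4, 3))
    df = rank_features(phi, ["a", "b", "c"])
    assert df["feature"].tolist() == ["a", "b", "c"]  # schema order on ties
    phi = np.array([[0.1, -0.5, 0.2], [0.1, 0.5, -0.2]])
    df = rank_features(phi, ["a", "b", "c"])
    assert df["feature"].tolist() == ["b", "c", "a"]
    shuffled = rank_features(phi[::-1], ["a", "b", "c"])
    assert shuffled["feature"].tolist() == df["feature"].tolist()


def test_beeswarm_table_shape_and_sign():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(20, 2))
    phi = np.column_stack([vals[:, 0] * 0.5, -vals[:, 1] * 0.5])
    df = export_beeswarm_table(phi, vals, [f"s{i}" for i in range(20)], ["f1", "f2"])
    assert len(df) == 40
    assert df["color_rank"].between(0, 1).all()
    sign = df.groupby("feature")["sign_summary"].first()
    assert sign["f1"] > 0.9 and sign["f2"] < -0.9
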