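"""Sparse-solver and decoding-model tests against independent oracles."""

import numpy as np
import pytest

from neurorecon.decode import (
    LayerDecoder,
    fit_l1,
    fit_layer_decoders,
    fit_romp,
)
from neurorecon.synthdata import make_sparse_problem


# ---------------------------------------------------------------------------
# ROMP


def test_romp_zero_target_gives_empty_model():
    x = np.random.default_rng(0).standard_normal((10, 5))
    m = fit_romp(x, np.zeros(10))
    assert m.support.size == 0
    assert np.all(m.weights == 0.0)


def test_romp_orthonormal_design_two_spikes():
    """Identity design, y = (0,3,0,-2,0): support {1,3}, weights (3,-2)."""
    x = np.eye(5)
    y = np.array([0.0, 3.0, 0.0, -2.0, 0.0])
    m = fit_romp(x, y, s=2)
    np.testing.assert_array_equal(m.support, [1, 3])
    np.testing.assert_allclose(m.weights[[1, 3]], [3.0, -2.0], atol=1e-12)
    assert m.residual_norm < 1e-10


def test_romp_nonfinite_rejected():
    x = np.ones((4, 3))
    x[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_romp(x, np.ones(4))


def test_romp_exact_recovery_planted():
    """Noiseless planted supports are recovered exactly with zero residual."""
    hits = 0
    for seed in range(25):
        x, y, w = make_sparse_problem(128, 256, 8, 0.0, seed)
        m = fit_romp(x, y, s=8)
        if np.array_equal(m.support, np.flatnonzero(w)):
            hits += 1
            assert m.residual_norm < 1e-8
    assert hits >= 24


def test_romp_support_growth_and_residual_monotonicity():
    """Support grows each iteration and the refit residual never increases."""
    x, y, _ = make_sparse_problem(60, 120, 6, 0.1, seed=3)

    # re-run the iteration manually via decreasing max_support budgets
    prev_support = -1
    prev_res = np.inf
    for budget in (2, 4, 6, 8, 10, 12):
        m = fit_romp(x, y, s=2, max_support=budget, res_tol=0.0)
        assert len(m.support) <= budget
        assert len(m.support) >= prev_support
        assert m.residual_norm <= prev_res + 1e-10
        prev_support = len(m.support)
        prev_res = m.residual_norm


def test_romp_recovery_f1_degrades_with_noise():
    """Mean support-recovery F1 is non-increasing in the noise level."""
    def f1(m_supp, true):
        tp = len(set(m_supp) & set(true))
        if tp == 0:
            return 0.0
        prec = tp / len(m_supp)
        rec = tp / len(true)
        return 2 * prec * rec / (prec + rec)

    means = []
    for noise in (0.0, 0.3, 1.0, 3.0):
        scores = []
        for seed in range(15):
            x, y, w = make_sparse_problem(64, 128, 5, noise, seed)
            m = fit_romp(x, y, s=5)
            scores.append(f1(m.support, np.flatnonzero(w)))
        means.append(np.mean(scores))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# L1


def test_l1_zero_target():
    x = np.random.default_rng(0).standard_normal((10, 5))
    m = fit_l1(x, np.zeros(10))
    assert m.support.size == 0


def test_l1_negative_lambda_rejected():
    with pytest.raises(ValueError, match="lambda"):
        fit_l1(np.eye(3), np.ones(3), lam=-1.0)


def test_l1_orthonormal_soft_thresholding():
    """On an orthonormal design the Lasso solution is soft(X'y, lambda)."""
    rng = np.random.default_rng(5)
    q, _ = np.linalg.qr(rng.standard_normal((30, 12)))
    y = q @ (2 * rng.standard_normal(12)) + 0.1 * rng.standard_normal(30)
    lam = 0.3
    m = fit_l1(q, y, lam=lam, fit_intercept=False)
    target = q.T @ y
    expected = np.sign(target) * np.maximum(np.abs(target) - lam, 0.0)
    np.testing.assert_allclose(m.weights[:-1], expected, atol=1e-10)


def test_l1_penalized_matches_coordinate_descent_oracle():
    """MFISTA objective agrees with an independent coordinate-descent solver."""
    from sklearn.linear_model import Lasso

    lam = 0.05
    for seed in range(10):
        x, y, _ = make_sparse_problem(15, 18, 3, 0.05, seed)
        m = fit_l1(x, y, lam=lam, fit_intercept=False, tol=1e-12, max_iter=20000)

        def obj(w):
            r = x @ w - y
            return 0.5 * r @ r + lam * np.abs(w).sum()

        oracle = Lasso(alpha=lam / 15, fit_intercept=False,
                       tol=1e-14, max_iter=200000).fit(x, y)
        assert abs(obj(m.weights[:-1]) - obj(oracle.coef_)) < 1e-6


def test_l1_objective_trace_nonincreasing():
    from neurorecon.decode import _lasso_objective, _mfista

    x, y, _ = make_sparse_problem(30, 50, 4, 0.1, seed=2)
    _, trace, _, _ = _mfista(x, y, 0.05, np.zeros(50), 1e-12, 500)
    assert np.all(np.diff(trace) <= 1e-12)


def test_l1_equality_mode_recovers_noiseless_signal():
    x, y, w = make_sparse_problem(60, 100, 5, 0.0, seed=1)
    m = fit_l1(x, y, mode="equality")
    assert np.max(np.abs(m.weights[:-1] - w)) < 1e-5
    assert m.residual_norm < 1e-5


def test_l1_nonconvergence_is_flagged_not_silent():
    x, y, _ = make_sparse_problem(40, 80, 5, 0.1, seed=4)
    m = fit_l1(x, y, lam=1e-6, tol=1e-14, max_iter=3)
    assert not m.converged


def test_solvers_agree_on_orthonormal_design():
    """ROMP and L1 reduce to the same solution at matched sparsity."""
    rng = np.random.default_rng(8)
    q, _ = np.linalg.qr(rng.standard_normal((40, 10)))
    w_true = np.zeros(10)
    w_true[[2, 7]] = [3.0, -2.0]
    y = q @ w_true
    m_romp = fit_romp(q, y, s=2)
    lam = 0.5
    m_l1 = fit_l1(q, y, lam=lam, fit_intercept=False)
    debiased = np.where(m_l1.weights[:-1] != 0,
                        m_l1.weights[:-1] + lam * np.sign(m_l1.weights[:-1]), 0.0)
    np.testing.assert_array_equal(m_romp.support, m_l1.support)
    np.testing.assert_allclose(m_romp.weights[:-1], debiased, atol=1e-8)


# ---------------------------------------------------------------------------
# layer decoder (Model -> fit -> Results)


def _toy_layer_problem(noise=0.0, d=6, m=80, n=30, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((m, n))
    w = np.zeros((n, d))
    for j in range(d):
        supp = rng.choice(n, size=2, replace=False)
        w[supp, j] = rng.uniform(1, 2, 2) * rng.choice([-1, 1], 2)
    f = x @ w + noise * rng.standard_normal((m, d))
    return x, f, w


def test_single_feature_set_matches_direct_fit():
    x, f, _ = _toy_layer_problem(d=1)
    res = LayerDecoder(f, x, solver="romp", s=2).fit()
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    direct = fit_romp(z, f[:, 0], s=2)
    np.testing.assert_array_equal(res.models[0].support, direct.support)
    np.testing.assert_allclose(res.models[0].weights, direct.weights)


def test_noiseless_supports_recovered_for_every_feature():
    x, f, w = _toy_layer_problem(noise=0.0, seed=3)
    res = fit_layer_decoders(x, f, solver="romp", s=2)
    for j, m in enumerate(res.models):
        np.testing.assert_array_equal(m.support, np.flatnonzero(w[:, j]))


def test_constant_feature_flagged_and_predicts_constant():
    x, f, _ = _toy_layer_problem(seed=4)
    f[:, 2] = 3.14
    res = fit_layer_decoders(x, f, solver="romp", s=2)
    assert list(res.excluded) == [2]
    pred = res.predict(x[:5])
    np.testing.assert_allclose(pred[:, 2], 3.14)


def test_training_prediction_identity_at_zero_noise():
    x, f, _ = _toy_layer_problem(noise=0.0, seed=5)
    res = fit_layer_decoders(x, f, solver="romp", s=2)
    np.testing.assert_allclose(res.predict(x), f, atol=1e-8)


def test_prediction_invariant_to_consistent_voxel_permutation():
    x, f, _ = _toy_layer_problem(seed=6)
    res = fit_layer_decoders(x, f, solver="romp", s=2)
    x_new = np.random.default_rng(7).standard_normal((9, x.shape[1]))
    base = res.predict(x_new)
    perm = np.random.default_rng(8).permutation(x.shape[1])
    res_p = fit_layer_decoders(x[:, perm], f, solver="romp", s=2)
    np.testing.assert_allclose(res_p.predict(x_new[:, perm]), base, atol=1e-8)


def test_predict_rejects_wrong_voxel_count():
    x, f, _ = _toy_layer_problem()
    res = fit_layer_decoders(x, f, solver="romp", s=2)
    with pytest.raises(ValueError, match="voxels"):
        res.predict(x[:, :-1])


def test_results_summary_and_json_roundtrip():
    x, f, _ = _toy_layer_problem(seed=9)
    res = fit_layer_decoders(x, f, solver="romp", s=2, layer="mpool1")
    s = res.summary()
    assert s.loc[0, "layer"] == "mpool1"
    assert s.loc[0, "n_features"] == f.shape[1]
    from neurorecon.decode import LayerDecoderResults

    back = LayerDecoderResults.from_json_dict(res.to_json_dict())
    np.testing.assert_allclose(back.predict(x), res.predict(x), atol=1e-12)
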