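"""Weighted-LASSO coordinate descent: closed-form oracles, KKT conditions,
kernel weighting and local-vs-global behaviour."""

import numpy as np
import pytest

from emrcost.errors import ConfigError, DomainError
from emrcost.lwlasso import (
    LocallyWeightedLasso,
    LWLassoConfig,
    cv_lambda,
    fit,
    kernel_weights,
    lambda_max,
    soft_threshold,
)


def _standardize(X, w):
    wsum = w.sum()
    mu = (w @ X) / wsum
    sd = np.sqrt((w @ (X - mu) ** 2) / wsum)
    return (X - mu) / sd


def test_soft_threshold():
    assert soft_threshold(3.0, 1.0) == 2.0
    assert soft_threshold(-3.0, 1.0) == -2.0
    assert soft_threshold(0.5, 1.0) == 0.0


def test_kernel_weights_scalar_oracle():
    X = np.array([[0.0], [1.0], [2.0]])
    w = kernel_weights(np.array([0.0]), X, tau=1.0)
    np.testing.assert_allclose(w, [1.0, np.exp(-0.5), np.exp(-2.0)], rtol=1e-12)
    assert np.all((0 < w) & (w <= 1))
    with pytest.raises(DomainError):
        kernel_weights(np.array([0.0]), X, tau=0.0)


def test_kernel_tends_to_one_for_large_bandwidth():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    w = kernel_weights(X[0], X, tau=1e9)
    np.testing.assert_allclose(w, 1.0, atol=1e-12)


def test_lambda_zero_is_weighted_ols():
    """With no penalty the fit equals weighted least squares (computed
    independently via sqrt-weight rescaling and lstsq)."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=60)
    for w in (np.ones(60), rng.uniform(0.1, 2.0, size=60)):
        m = fit(X, y, weights=w, config=LWLassoConfig(lam=0.0, tol=1e-10))
        A = np.column_stack([np.ones(60), X]) * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
        np.testing.assert_allclose(np.r_[m.beta0, m.beta], coef, atol=1e-8)


def test_full_shrinkage_at_lambda_max():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 4))
    y = X @ np.array([2.0, 0.0, -1.0, 0.5]) + rng.normal(size=50)
    w = rng.uniform(0.5, 1.5, size=50)
    lmax = lambda_max(X, y, w)
    m = fit(X, y, weights=w, config=LWLassoConfig(lam=lmax * (1 + 1e-10)))
    np.testing.assert_allclose(m.beta, 0.0, atol=1e-12)
    assert m.beta0 == pytest.approx(float(w @ y / w.sum()), abs=1e-12)
    # just below lambda_max at least one coefficient activates
    m2 = fit(X, y, weights=w, config=LWLassoConfig(lam=lmax * 0.95))
    assert np.abs(m2.beta).max() > 0


def test_orthonormal_design_soft_thresholding_closed_form():
    """On a centered orthonormal design (columns mean 0, X'X/m = I) the
    solution is soft(beta_ols_j, lam/m) coordinate-wise."""
    rng = np.random.default_rng(3)
    m_rows = 64
    A = rng.normal(size=(m_rows, 6))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = Q * np.sqrt(m_rows)            # columns: mean ~0, sum of squares = m
    beta_true = np.array([3.0, -2.0, 0.3, 0.0, 1.0, -0.2])
    y = 1.5 + X @ beta_true + rng.normal(size=m_rows) * 0.5
    yc = y - y.mean()
    beta_ols = X.T @ yc / m_rows
    for lam_over_m in (0.05, 0.5, 1.5):
        lam = lam_over_m * m_rows
        model = fit(X, y, config=LWLassoConfig(lam=lam, tol=1e-12))
        expected = soft_threshold(beta_ols, lam_over_m)
        np.testing.assert_allclose(model.beta, expected, atol=1e-8)


def test_matches_sklearn_on_standardized_design():
    """Independent cross-check: on a pre-standardized design our objective
    coincides with scikit-learn's Lasso(alpha = lam/m)."""
    from sklearn.linear_model import Lasso

    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 7))
    X = _standardize(X, np.ones(80))
    y = X @ np.array([2.0, 0.0, -1.5, 0.0, 0.7, 0.0, 3.0]) + rng.normal(size=80)
    lam = 24.0
    ours = fit(X, y, config=LWLassoConfig(lam=lam, tol=1e-12))
    ref = Lasso(alpha=lam / 80, fit_intercept=True, tol=1e-12, max_iter=100000)
    ref.fit(X, y)
    np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-6)
    assert ours.beta0 == pytest.approx(ref.intercept_, abs=1e-6)


def test_kkt_conditions_on_random_problems():
    """Subgradient optimality at convergence: active coordinates meet the
    stationarity equality, inactive ones respect the bound."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(20, 60))
        p = int(rng.integers(2, 8))
        X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
        beta = np.where(rng.random(p) < 0.5, rng.normal(size=p) * 2, 0.0)
        y = 1.0 + X @ beta + rng.normal(size=n)
        w = rng.uniform(0.2, 2.0, size=n)
        lam = rng.uniform(0.05, 0.9) * lambda_max(X, y, w)
        model = fit(X, y, weights=w, config=LWLassoConfig(lam=lam, tol=1e-10))
        Xs = _standardize(X, w)
        beta_s = model.beta * np.sqrt((w @ (X - (w @ X) / w.sum()) ** 2) / w.sum())
        r = (y - (w @ y / w.sum())) - Xs @ beta_s
        grad = (w * r) @ Xs / n
        tol = 1e-6
        for j in range(p):
            if beta_s[j] == 0.0:
                assert abs(grad[j]) <= lam / n + tol
            else:
                assert grad[j] == pytest.approx(np.sign(beta_s[j]) * lam / n,
                                                abs=tol)


def test_objective_non_increasing_and_support_monotone_in_lambda():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(100, 10))
    y = X @ np.r_[np.array([3.0, -2.0, 1.0]), np.zeros(7)] + rng.normal(size=100)
    lmax = lambda_max(X, y)
    nnz = []
    for lam in np.geomspace(lmax, lmax * 1e-3, 10):
        model = fit(X, y, config=LWLassoConfig(lam=lam))
        path = model.objective_path
        assert np.all(np.diff(path) <= 1e-10)
        nnz.append(int(np.count_nonzero(model.beta)))
    assert all(b >= a for a, b in zip(nnz, nnz[1:]))  # support grows as lam drops


def test_sigma_cap_enforces_coefficient_budget():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 4))
    y = X @ np.array([4.0, -3.0, 2.0, 1.0]) + rng.normal(size=60)
    free = fit(X, y, config=LWLassoConfig(lam=0.0))
    budget = 0.5 * np.abs(free.beta).sum()
    capped = fit(X, y, config=LWLassoConfig(lam=0.0, sigma_cap=budget))
    assert np.abs(capped.beta).sum() <= budget * (1 + 1e-6)
    assert capped.lam > 0
    # a slack budget leaves the unpenalized solution untouched
    loose = fit(X, y, config=LWLassoConfig(lam=0.0, sigma_cap=10 * budget))
    np.testing.assert_allclose(loose.beta, free.beta, atol=1e-8)


def test_penalty_weighting_mode():
    """Per-coefficient penalty weights: an infinitely cheap coordinate is
    not shrunk at all relative to loss-weighted shrinkage of the others."""
    rng = np.random.default_rng(8)
    X = _standardize(rng.normal(size=(80, 3)), np.ones(80))
    y = X @ np.array([2.0, 2.0, 2.0]) + rng.normal(size=80) * 0.1
    lam = 40.0
    pw = np.array([0.0, 1.0, 1.0])
    m = fit(X, y, config=LWLassoConfig(lam=lam, weighting="penalty"),
            penalty_weights=pw)
    base = fit(X, y, config=LWLassoConfig(lam=lam))
    assert abs(m.beta[0]) > abs(base.beta[0])
    assert abs(m.beta[1] - base.beta[1]) < 0.2
    with pytest.raises(ConfigError):
        fit(X, y, weights=np.ones(80),
            config=LWLassoConfig(lam=1.0, weighting="penalty"))


def test_zero_variance_feature_coefficient_is_zero():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 3))
    X[:, 1] = 2.5
    y = X[:, 0] * 2 + rng.normal(size=40)
    with pytest.warns(UserWarning, match="zero-variance"):
        m = fit(X, y, config=LWLassoConfig(lam=1.0))
    assert m.beta[1] == 0.0


def test_nonfinite_and_mismatched_inputs_rejected():
    with pytest.raises(DomainError):
        fit(np.array([[1.0, np.nan]]), np.array([1.0]))
    m = fit(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))
    with pytest.raises(DomainError):
        m.predict(np.ones((3, 5)))


def test_local_prediction_beats_global_on_curved_data():
    """30-point 1-D quadratic: query-local Gaussian-weighted refits track the
    curvature that a single global linear-in-x fit cannot."""
    rng = np.random.default_rng(10)
    x = np.linspace(-1, 1, 30)
    y = 2.0 * x**2 + rng.normal(size=30) * 0.05
    X = x[:, None]
    local = LocallyWeightedLasso(lam=0.001, tau=0.3).fit(X, y)
    pred_local = local.predict(X, local=True)
    pred_global = local.predict(X, local=False)
    assert np.mean((pred_local - y) ** 2) < np.mean((pred_global - y) ** 2)


def test_infinite_bandwidth_reduces_to_global_lasso():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(50, 4))
    y = X @ np.array([1.0, 0.0, -2.0, 0.5]) + rng.normal(size=50)
    model = LocallyWeightedLasso(lam=5.0, tau=1e9).fit(X, y)
    queries = rng.normal(size=(10, 4))
    np.testing.assert_allclose(
        model.predict(queries, local=True),
        model.predict(queries, local=False),
        atol=1e-6,
    )


def test_cv_lambda_validates_and_is_deterministic():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(50, 5))
    y = X @ np.array([2.0, 0.0, 0.0, 1.0, 0.0]) + rng.normal(size=50)
    assert cv_lambda(X, y, seed=3) == cv_lambda(X, y, seed=3)
    with pytest.raises(ConfigError):
        cv_lambda(X, y, n_folds=1)
    with pytest.raises(ConfigError):
        cv_lambda(X, y, objective="huber")


def test_config_validation():
    with pytest.raises(ConfigError):
        LWLassoConfig(lam=-1.0)
    with pytest.raises(ConfigError):
        LWLassoConfig(tau=-2.0)
    with pytest.raises(ConfigError):
        LWLassoConfig(tol=0.0)
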