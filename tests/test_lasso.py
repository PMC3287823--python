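import numpy as np
import pytest

import raremark as rm
from raremark.lasso import (
    LassoFit,
    PathSpec,
    _loglik,
    compute_lambda_max,
    fit_lasso_logistic,
    fit_unpenalized_logistic,
)


def make_data(seed=0, n=200, k=8, assoc=None):
    rng = np.random.default_rng(seed)
    D = (rng.uniform(size=(n, k)) < 0.1).astype(float)
    Z = np.column_stack([rng.normal(50, 10, n), rng.integers(0, 2, n)])
    eta = -0.8 + 0.01 * (Z[:, 0] - 50) + 0.3 * Z[:, 1]
    if assoc:
        for j, b in assoc.items():
            eta = eta + b * D[:, j]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return D, Z, y


def test_all_penalized_coefficients_zero_at_lambda_max():
    D, Z, y = make_data(1)
    fit = fit_lasso_logistic(D, Z, y, PathSpec(n_lambdas=20))
    assert np.count_nonzero(fit.dummy_coefs[0]) == 0


def test_lambda_max_matches_numerical_gradient():
    """lambda_max equals the largest |d loglik / d beta_j| over dummies at
    the covariates-only optimum, checked by central finite differences."""
    D, Z, y = make_data(2)
    lam_max = compute_lambda_max(D, Z, y)
    beta0 = fit_unpenalized_logistic(Z, y)
    n = len(y)
    X0 = np.column_stack([np.ones(n), Z])
    eps = 1e-5
    grads = []
    for j in range(D.shape[1]):
        up = _loglik(X0 @ beta0 + eps * D[:, j], y.astype(float))
        dn = _loglik(X0 @ beta0 - eps * D[:, j], y.astype(float))
        grads.append((up - dn) / (2 * eps))
    assert lam_max == pytest.approx(max(abs(g) for g in grads), rel=1e-4)


def test_strongest_dummy_enters_path_first():
    """A dummy perfectly aligned with the phenotype has the largest score at
    the null fit and is the first coefficient to leave zero."""
    rng = np.random.default_rng(3)
    n = 150
    y = rng.binomial(1, 0.4, n)
    D = (rng.uniform(size=(n, 11)) < 0.08).astype(float)
    D[:, 0] = y  # perfectly correlated column
    fit = fit_lasso_logistic(D, None, y.astype(float), PathSpec(n_lambdas=40))
    first = next(i for i in range(len(fit.lambdas))
                 if np.count_nonzero(fit.dummy_coefs[i]))
    active = np.nonzero(fit.dummy_coefs[first])[0]
    assert list(active) == [0]


def test_kkt_certificate_along_path():
    for seed in (4, 5):
        D, Z, y = make_data(seed, assoc={0: 1.2, 3: -0.9})
        fit = fit_lasso_logistic(D, Z, y)
        assert fit.converged.all()
        assert fit.kkt_violation.max() <= 1e-6  # mean-gradient scale


def test_loglik_nondecreasing_as_penalty_relaxes():
    D, Z, y = make_data(6, assoc={1: 1.0})
    fit = fit_lasso_logistic(D, Z, y, PathSpec(n_lambdas=50))
    assert (np.diff(fit.loglik) >= -1e-6).all()


def _fit_from(loglik, k):
    L = len(loglik)
    return LassoFit(
        lambdas=np.linspace(1.0, 0.1, L),
        intercept=np.zeros(L),
        cov_coefs=np.zeros((L, 0)),
        dummy_coefs=np.zeros((L, 1)),
        loglik=np.asarray(loglik, float),
        n_nonzero=np.asarray(k),
        kkt_violation=np.zeros(L),
        converged=np.ones(L, bool),
    )


def test_aic_selection_arithmetic_and_ties():
    # AIC = 2k - 2l: (-100,5)->210, (-95,6)->202, (-94.9,7)->203.8
    fit = _fit_from([-100.0, -95.0, -94.9], [5, 6, 7])
    np.testing.assert_allclose(fit.aic, [210.0, 202.0, 203.8])
    assert fit.selected == 1
    # single-point path
    assert _fit_from([-10.0], [2]).selected == 0
    # exact tie -> the larger-penalty (sparser) point
    assert _fit_from([-10.0, -11.0], [3, 2]).selected == 0


def test_matches_independent_l1_solver():
    """Cross-check a mid-path solution against statsmodels' L1-penalized
    logistic fit with a per-coefficient penalty vector."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(8)
    n, k = 150, 5
    D = (rng.uniform(size=(n, k)) < 0.15).astype(float)
    Z = rng.normal(size=(n, 1))
    eta = -0.5 + 1.2 * D[:, 0] - 0.8 * D[:, 2] + 0.4 * Z[:, 0]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    fit = fit_lasso_logistic(D, Z, y.astype(float), PathSpec(n_lambdas=30))
    for i in (10, 15, 20):
        lam = fit.lambdas[i]
        X = sm.add_constant(np.column_stack([Z, D]))
        alpha = np.r_[0.0, 0.0, np.full(k, lam)]
        res = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=alpha, disp=0, acc=1e-10, trim_mode="auto"
        )
        ours = np.r_[fit.intercept[i], fit.cov_coefs[i], fit.dummy_coefs[i]]
        np.testing.assert_allclose(ours, res.params, atol=5e-3)


def test_phenotype_must_have_both_classes():
    D = np.zeros((10, 2))
    with pytest.raises(ValueError, match="cases and controls"):
        fit_lasso_logistic(D, None, np.ones(10))
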