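"""L1-penalized logistic regression with an unpenalized covariate block.

Solves, for each penalty value on a decreasing path,

    maximize  l(b0, b_Z, b_D)  -  lam * ||b_D||_1

where ``l`` is the Bernoulli log-likelihood, ``Z`` the covariate design
(never penalized, like the intercept) and ``D`` the carrier-dummy block
subject to selection. The solver is proximal Newton: each outer step forms
the iteratively-reweighted least-squares surrogate and minimizes it by
cyclic coordinate descent with soft-thresholding on the penalized block,
warm-starting along the path.

``lambda_max`` — the smallest penalty at which every penalized coefficient
is zero — is the largest absolute score of a dummy at the covariates-only
fit, ``max_j |D_j' (y - p_hat)|``. The path is ``n_lambdas`` log-spaced
values from ``lambda_max`` down to ``lambda_min_ratio * lambda_max``.

Every path point is certified against the Karush-Kuhn-Tucker conditions of
the exact (non-surrogate) problem:

* zero penalized coefficient:    |g_j| <= lam + tol
* nonzero penalized coefficient: |g_j - lam * sign(b_j)| <= tol
* unpenalized coefficient:       |g_j| <= tol

with ``g = X'(y - p)`` and ``tol`` expressed per observation
(``kkt_tol * n``), i.e. 1e-6 on the mean-gradient scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: hard cap on |coefficient| to keep quasi-separated fits finite
COEF_CAP = 30.0


@dataclass
class PathSpec:
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.001
    kkt_tol: float = 1e-6  # per-observation (mean-gradient) scale
    max_outer: int = 100
    max_inner: int = 1000


@dataclass
class LassoFit:
    """One regularization path: coefficients, likelihoods, AIC selection."""

    lambdas: np.ndarray                # decreasing
    intercept: np.ndarray              # (L,)
    cov_coefs: np.ndarray              # (L, n_cov)
    dummy_coefs: np.ndarray            # (L, K)
    loglik: np.ndarray                 # (L,) total Bernoulli log-likelihood
    n_nonzero: np.ndarray              # (L,) incl. intercept + covariates
    kkt_violation: np.ndarray          # (L,) max violation, mean-grad scale
    converged: np.ndarray              # (L,) bool
    selected: int = field(init=False)

    def __post_init__(self) -> None:
        self.selected = int(np.argmin(self.aic))  # argmin -> first (largest lam)

    @property
    def aic(self) -> np.ndarray:
        return 2.0 * self.n_nonzero - 2.0 * self.loglik


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _kkt_violation(
    X: np.ndarray, y: np.ndarray, eta: np.ndarray, beta: np.ndarray,
    penalized: np.ndarray, lam: float,
) -> float:
    g = X.T @ (y - _sigmoid(eta))
    viol = np.abs(g.copy())
    pen_zero = penalized & (beta == 0)
    pen_nz = penalized & (beta != 0)
    viol[pen_zero] = np.maximum(np.abs(g[pen_zero]) - lam, 0.0)
    viol[pen_nz] = np.abs(g[pen_nz] - lam * np.sign(beta[pen_nz]))
    return float(viol.max()) if len(viol) else 0.0


def _solve_one(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray,
    penalized: np.ndarray, lam: float, spec: PathSpec,
) -> tuple[np.ndarray, bool]:
    """Proximal-Newton solve at one penalty, warm-started from ``beta``."""
    n, p = X.shape
    tol_total = spec.kkt_tol * n
    xsq = X**2
    capped = False

    def cd_pass(b: np.ndarray, r: np.ndarray, w: np.ndarray, wx2: np.ndarray,
                idx: np.ndarray) -> float:
        nonlocal capped
        max_step = 0.0
        for j in idx:
            if wx2[j] <= 0.0:
                continue
            gj = float(X[:, j] @ r) + wx2[j] * b[j]
            new = _soft(gj, lam) / wx2[j] if penalized[j] else gj / wx2[j]
            if abs(new) > COEF_CAP:
                new = np.sign(new) * COEF_CAP
                capped = True
            step = new - b[j]
            if step != 0.0:
                r -= step * w * X[:, j]
                b[j] = new
                max_step = max(max_step, abs(step))
        return max_step

    all_idx = np.arange(p)
    for _ in range(spec.max_outer):
        eta = X @ beta
        prob = _sigmoid(eta)
        w = np.maximum(prob * (1.0 - prob), 1e-5)
        wx2 = w @ xsq
        # coordinate descent on the quadratic surrogate; r tracks w*(z - eta)
        r = y - prob
        b = beta.copy()
        cd_pass(b, r, w, wx2, all_idx)  # one full sweep sets the active set
        for _ in range(spec.max_inner):
            active = np.where((b != 0) | ~penalized)[0]
            for _ in range(spec.max_inner):
                if cd_pass(b, r, w, wx2, active) < 1e-9:
                    break
            if cd_pass(b, r, w, wx2, all_idx) < 1e-9:
                break
        beta = b
        if _kkt_violation(X, y, X @ beta, beta, penalized, lam) <= tol_total:
            break
    if capped:
        logger.warning("coefficient cap %.0f hit at lambda=%.4g", COEF_CAP, lam)
    viol = _kkt_violation(X, y, X @ beta, beta, penalized, lam)
    return beta, bool(viol <= tol_total and not capped)


def _standardize(Z: np.ndarray | None) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Center/scale covariate columns (conditioning only; the optimum of the
    penalized problem is invariant to affine maps of the unpenalized block)."""
    if Z is None or Z.size == 0:
        return None, np.array([]), np.array([])
    mean = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    return (Z - mean) / scale, mean, scale


def _fit_null(Zs: np.ndarray | None, y: np.ndarray, spec: PathSpec) -> np.ndarray:
    """Covariates-only logistic fit in standardized coordinates."""
    n = len(y)
    X = np.column_stack([np.ones(n)] + ([Zs] if Zs is not None else []))
    beta = np.zeros(X.shape[1])
    beta, ok = _solve_one(X, y, beta, np.zeros(X.shape[1], bool), 0.0, spec)
    if not ok:
        raise RuntimeError("covariates-only logistic fit did not converge")
    return beta


def fit_unpenalized_logistic(Z: np.ndarray | None, y: np.ndarray) -> np.ndarray:
    """Plain logistic fit on intercept + covariates (no penalty).

    Returns the coefficient vector for the raw design ``[1, Z]``.
    """
    Zs, mean, scale = _standardize(np.asarray(Z, float) if Z is not None else None)
    beta = _fit_null(Zs, y, PathSpec())
    if Zs is None:
        return beta
    out = beta.copy()
    out[1:] = beta[1:] / scale
    out[0] = beta[0] - float(np.sum(beta[1:] * mean / scale))
    return out


def compute_lambda_max(
    dummies: np.ndarray, covariates: np.ndarray | None, y: np.ndarray
) -> float:
    """Smallest penalty zeroing every dummy: max |score| at the null fit."""
    Zs, _, _ = _standardize(
        np.asarray(covariates, float) if covariates is not None else None
    )
    beta0 = _fit_null(Zs, np.asarray(y, float), PathSpec())
    n = len(y)
    Xz = np.column_stack([np.ones(n)] + ([Zs] if Zs is not None else []))
    resid = y - _sigmoid(Xz @ beta0)
    if dummies.shape[1] == 0:
        return 0.0
    return float(np.max(np.abs(np.asarray(dummies, float).T @ resid)))


def fit_lasso_logistic(
    dummies: np.ndarray,
    covariates: np.ndarray | None,
    phenotype: np.ndarray,
    path_spec: PathSpec | None = None,
) -> LassoFit:
    """Fit the full penalized path for one variant group.

    ``dummies`` is the N x K 0/1 carrier matrix (penalized block);
    ``covariates`` the numeric covariate design (unpenalized; may be None).
    The phenotype must contain at least one case and one control.
    """
    spec = path_spec or PathSpec()
    y = np.asarray(phenotype, dtype=float)
    if y.min() == y.max():
        raise ValueError("phenotype needs both cases and controls")
    D = np.asarray(dummies, dtype=float)
    n, K = D.shape
    Z = None
    n_cov = 0
    if covariates is not None and np.asarray(covariates).size:
        Z = np.asarray(covariates, dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), Z])) < Z.shape[1] + 1:
            raise ValueError("covariate design (with intercept) is rank deficient")
        n_cov = Z.shape[1]
    Zs, z_mean, z_scale = _standardize(Z)

    lam_max = compute_lambda_max(D, Z, y)
    if lam_max <= 0:
        lam_max = 1e-10  # degenerate group: dummies carry no score at the null
    lams = np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * spec.lambda_min_ratio),
                    spec.n_lambdas)
    )

    cols = [np.ones(n)] + ([Zs] if Zs is not None else []) + [D]
    X = np.column_stack(cols)
    penalized = np.zeros(X.shape[1], bool)
    penalized[1 + n_cov :] = True

    L = len(lams)
    intercept = np.empty(L)
    cov_coefs = np.empty((L, n_cov))
    dummy_coefs = np.empty((L, K))
    loglik = np.empty(L)
    n_nonzero = np.empty(L, dtype=int)
    kkt = np.empty(L)
    conv = np.empty(L, dtype=bool)

    beta = np.zeros(X.shape[1])
    for i, lam in enumerate(lams):
        if i == 0:
            # at lambda_max the penalized block is zero by construction;
            # solve only the unpenalized part
            beta = np.zeros(X.shape[1])
            beta[: 1 + n_cov] = _fit_null(Zs, y, spec)
            ok = True
        else:
            beta, ok = _solve_one(X, y, beta, penalized, lam, spec)
        eta = X @ beta
        # back-transform the standardized covariate block to raw coordinates
        bz = beta[1 : 1 + n_cov]
        if n_cov:
            cov_coefs[i] = bz / z_scale
            intercept[i] = beta[0] - float(np.sum(bz * z_mean / z_scale))
        else:
            cov_coefs[i] = bz
            intercept[i] = beta[0]
        dummy_coefs[i] = beta[1 + n_cov :]
        loglik[i] = _loglik(eta, y)
        n_nonzero[i] = int(np.count_nonzero(beta))
        kkt[i] = _kkt_violation(X, y, eta, beta, penalized, lam) / n
        conv[i] = ok
        if not ok:
            logger.warning("path point %d (lambda=%.4g) not certified", i, lam)

    return LassoFit(
        lambdas=lams,
        intercept=intercept,
        cov_coefs=cov_coefs,
        dummy_coefs=dummy_coefs,
        loglik=loglik,
        n_nonzero=n_nonzero,
        kkt_violation=kkt,
        converged=conv,
    )


def select_by_aic(fit: LassoFit) -> tuple[float, np.ndarray, np.ndarray]:
    """Coefficients at the AIC-minimizing path point.

    AIC = 2k - 2l with k counting all nonzero coefficients (intercept and
    covariates included — a constant offset across the path, kept for
    reproducibility). Exact ties go to the larger (sparser) penalty.
    Returns (lambda, covariate coefficients incl. intercept, dummy weights).
    """
    i = fit.selected
    return (
        float(fit.lambdas[i]),
        np.concatenate([[fit.intercept[i]], fit.cov_coefs[i]]),
        fit.dummy_coefs[i].copy(),
    )
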