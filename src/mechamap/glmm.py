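"""Gamma GLMM fitted by penalized quasi-likelihood (PQL).

Model: observations y_i > 0 with conditional mean mu_i and gamma variance
mu_i^2 * phi, linked by log mu = X beta + sum_c Z_c b_c, with independent
Gaussian random intercepts b_c ~ N(0, sigma_c^2 I) per grouping factor c
(patient, map, map x tissue, ...).

PQL iterates a working-response linearization of the GLM around the current
linear predictor eta:

    y* = eta + (y - mu) / mu            (log link: d eta / d mu = 1/mu)

For the gamma family with log link the IRLS working weights
(d mu/d eta)^2 / V(mu) = mu^2 / mu^2 are identically one, so each PQL step
is an *unweighted* Gaussian linear mixed model on y*. That LMM is solved by
profiled REML over the variance ratios lambda_c = sigma_c^2 / sigma_e^2
using the mixed-model equations; because X'X, X'Z and Z'Z do not change
across iterations they are formed once, making each REML evaluation a
single Cholesky factorization of a (q x q) system.

The residual variance of the converged working model estimates the gamma
dispersion phi; a moment estimator from Pearson residuals is reported
alongside. Fixed-effect covariance is sigma_e^2 (X' V0^-1 X)^-1 from the
final working fit. Wald F tests with containment denominator degrees of
freedom live in :mod:`mechamap.stiffness_stats`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

_THETA_LO, _THETA_HI = -15.0, 10.0


@dataclass
class RandomTerm:
    """One random-intercept grouping factor."""

    name: str
    codes: np.ndarray  # int level code per observation
    n_levels: int

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        codes, uniques = pd_factorize(labels)
        return cls(name, codes, len(uniques))


def pd_factorize(labels):
    import pandas as pd
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.int64), uniques


def build_z(terms: Sequence[RandomTerm]) -> sparse.csr_matrix:
    n = len(terms[0].codes)
    blocks = []
    for t in terms:
        blocks.append(sparse.csr_matrix(
            (np.ones(n), (np.arange(n), t.codes)), shape=(n, t.n_levels)))
    return sparse.hstack(blocks).tocsr()


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray      # sigma_e^2 (X'V0^-1 X)^-1
    u: np.ndarray             # BLUPs, concatenated across terms
    sigma2_e: float
    lambdas: np.ndarray       # variance ratios per random term
    theta: np.ndarray         # log lambdas (optimizer state)
    reml_crit: float          # -2 restricted log-likelihood (up to const)
    converged: bool


class _REMLProblem:
    """Profiled REML objective over theta = log(lambda) with cached
    cross-products; supports refreshing the response cheaply (PQL)."""

    def __init__(self, X: np.ndarray, Z: sparse.csr_matrix,
                 sizes: Sequence[int]):
        self.X = X
        self.Z = Z
        self.sizes = np.asarray(sizes, dtype=int)
        self.n, self.p = X.shape
        self.q = int(self.sizes.sum())
        self.XtX = X.T @ X
        self.ZtX = (Z.T @ X)          # q x p dense
        if sparse.issparse(self.ZtX):
            self.ZtX = self.ZtX.toarray()
        self.ZtZ = (Z.T @ Z).toarray()
        self._ridge = 1e-10 * (np.trace(self.ZtZ) / max(self.q, 1) + 1.0)
        self.block = np.repeat(np.arange(len(sizes)), self.sizes)
        self.set_response(np.zeros(self.n))

    def set_response(self, y: np.ndarray):
        self.y = y
        self.Xty = self.X.T @ y
        self.Zty = self.Z.T @ y
        self.yty = float(y @ y)

    def _solve(self, theta: np.ndarray):
        lam = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        dinv = (1.0 / lam)[self.block]
        K = self.ZtZ + np.diag(dinv + self._ridge)
        cK = cho_factor(K, lower=True, check_finite=False)
        logdetK = 2.0 * float(np.sum(np.log(np.diag(cK[0]))))
        SZX = cho_solve(cK, self.ZtX, check_finite=False)   # q x p
        SZy = cho_solve(cK, self.Zty, check_finite=False)   # q
        A = self.XtX - self.ZtX.T @ SZX
        b = self.Xty - self.ZtX.T @ SZy
        cA = cho_factor(A + 1e-12 * np.eye(self.p) * max(
            np.trace(A) / self.p, 1.0), lower=True, check_finite=False)
        beta = cho_solve(cA, b, check_finite=False)
        yvy = self.yty - float(self.Zty @ SZy)
        rvr = max(yvy - float(beta @ b), 1e-300)
        sigma2 = rvr / (self.n - self.p)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
        logdetV0 = logdetK + float(np.sum(self.sizes * np.log(lam)))
        crit = (self.n - self.p) * np.log(sigma2) + logdetV0 + logdetA
        return crit, lam, beta, sigma2, cK, cA, b

    def objective(self, theta: np.ndarray) -> float:
        try:
            return self._solve(theta)[0]
        except np.linalg.LinAlgError:
            return 1e12

    def fit(self, theta0: Optional[np.ndarray] = None) -> LMMFit:
        n_comp = len(self.sizes)
        if n_comp == 0:
            return self._fit_fixed_only()
        theta0 = np.zeros(n_comp) if theta0 is None else np.asarray(
            theta0, dtype=float)
        theta0 = np.clip(theta0, _THETA_LO, _THETA_HI)
        res = minimize(self.objective, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7,
                                "maxiter": 300 * n_comp})
        theta = np.clip(res.x, _THETA_LO, _THETA_HI)
        crit, lam, beta, sigma2, cK, cA, b = self._solve(theta)
        cov_beta = sigma2 * cho_solve(
            cA, np.eye(self.p), check_finite=False)
        u = cho_solve(cK, self.Zty - self.ZtX @ beta, check_finite=False)
        return LMMFit(beta=beta, cov_beta=cov_beta, u=u, sigma2_e=sigma2,
                      lambdas=lam, theta=theta, reml_crit=crit,
                      converged=bool(res.success))

    def _fit_fixed_only(self) -> LMMFit:
        cA = cho_factor(self.XtX + 1e-12 * np.eye(self.p) * max(
            np.trace(self.XtX) / self.p, 1.0), lower=True,
            check_finite=False)
        beta = cho_solve(cA, self.Xty, check_finite=False)
        rss = max(self.yty - float(beta @ self.Xty), 0.0)
        sigma2 = rss / max(self.n - self.p, 1)
        cov_beta = sigma2 * cho_solve(cA, np.eye(self.p),
                                      check_finite=False)
        return LMMFit(beta=beta, cov_beta=cov_beta, u=np.zeros(0),
                      sigma2_e=sigma2, lambdas=np.zeros(0),
                      theta=np.zeros(0), reml_crit=np.nan, converged=True)


@dataclass
class PQLFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    u: np.ndarray
    eta: np.ndarray
    sigma2_working: float          # residual variance of the working LMM
    dispersion_pearson: float      # moment estimator from Pearson residuals
    random_variances: dict         # sigma_c^2 on the working scale
    n_iter: int
    converged: bool
    random_terms: list
    dropped_terms: list


def fit_gamma_pql(y: np.ndarray, X: np.ndarray,
                  random_terms: Sequence[RandomTerm],
                  tol: float = 1e-6, max_iter: int = 100) -> PQLFit:
    """Fit the gamma/log-link GLMM by PQL.

    Random terms with fewer than two levels are dropped (a one-level
    intercept is not identifiable); a singular component simply converges
    to the lower bound of its variance ratio.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma responses must be strictly positive")
    kept, dropped = [], []
    for t in random_terms:
        (kept if t.n_levels >= 2 else dropped).append(t)
    if dropped:
        logger.warning("dropping random terms with <2 levels: %s",
                       [t.name for t in dropped])
    n, p = X.shape
    if kept:
        Z = build_z(kept)
        problem = _REMLProblem(X, Z, [t.n_levels for t in kept])
    else:
        Z = None
        problem = _REMLProblem(X, sparse.csr_matrix((n, 0)), [])

    eta = np.log(y)
    beta_old = None
    theta = None
    fit = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -60.0, 60.0))
        ystar = eta + (y - mu) / mu
        problem.set_response(ystar)
        fit = problem.fit(theta0=theta)
        theta = fit.theta if len(fit.theta) else None
        eta = X @ fit.beta
        if Z is not None and len(fit.u):
            eta = eta + Z @ fit.u
        if beta_old is not None:
            denom = max(1.0, float(np.max(np.abs(fit.beta))))
            if float(np.max(np.abs(fit.beta - beta_old))) / denom < tol:
                converged = True
                break
        beta_old = fit.beta.copy()
    mu = np.exp(np.clip(eta, -60.0, 60.0))
    pearson = (y - mu) / mu
    phi = float(pearson @ pearson) / max(n - p, 1)
    rvar = {}
    if kept:
        for t, lam in zip(kept, fit.lambdas):
            rvar[t.name] = float(lam * fit.sigma2_e)
    return PQLFit(beta=fit.beta, cov_beta=fit.cov_beta, u=fit.u, eta=eta,
                  sigma2_working=float(fit.sigma2_e),
                  dispersion_pearson=phi, random_variances=rvar,
                  n_iter=it, converged=converged,
                  random_terms=[t.name for t in kept],
                  dropped_terms=[t.name for t in dropped])
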