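"""Poisson regression with a group-level random intercept.

Counts y_ij for observation i of group (subject) j follow

    y_ij ~ Poisson(mu_ij),  log mu_ij = x_ij' beta + offset_ij + b_j,
    b_j ~ Normal(0, sigma^2),

and the marginal likelihood integrates the random intercepts out with
adaptive Gauss-Hermite quadrature (each group's integrand is re-centred
at its posterior mode and re-scaled by its curvature before applying the
Hermite rule, which keeps the rule accurate even when per-group counts
are large and the integrand narrow). Maximum-likelihood estimates come
from quasi-Newton optimisation over (beta, log sigma); standard errors
from the finite-difference observed information. The exact marginal
log-likelihood makes BIC, and hence BIC-approximated Bayes factors,
well-defined for nested model comparison.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = ["PoissonMixedGLM"]


class PoissonMixedGLM(BaseEstimator):
    """Mixed-effects Poisson regression with one random intercept.

    Parameters
    ----------
    n_quad : int
        Number of Gauss-Hermite nodes per group (adaptive placement).
    sigma_floor : float
        Lower bound for the random-intercept SD; an estimate at the
        floor means the variance component is effectively zero.

    Attributes
    ----------
    coef_ : ndarray, fixed-effect estimates.
    coef_se_ : ndarray, Wald standard errors of the fixed effects.
    sigma_ : float, random-intercept SD.
    loglik_ : float, maximised marginal log-likelihood.
    bic_ : float, -2 loglik + n_params * log(n_obs).
    """

    def __init__(self, n_quad: int = 20, sigma_floor: float = 1e-4, maxiter: int = 500):
        self.n_quad = n_quad
        self.sigma_floor = sigma_floor
        self.maxiter = maxiter

    # ---- marginal likelihood -------------------------------------------

    def _loglik(self, params, X, y, codes, n_groups, offset, nodes, weights):
        """Adaptive GH marginal log-likelihood, vectorised across groups."""
        beta = params[:-1]
        sigma = np.exp(params[-1])
        eta0 = X @ beta + offset
        exp_eta0 = np.exp(eta0)
        sum_y = np.bincount(codes, weights=y, minlength=n_groups)
        const = float(np.sum(y * eta0 - gammaln(y + 1)))

        # Newton search for the per-group posterior modes of b
        b = np.zeros(n_groups)
        for _ in range(50):
            sum_mu = np.bincount(codes, weights=exp_eta0 * np.exp(b[codes]), minlength=n_groups)
            grad = sum_y - sum_mu - b / sigma**2
            hess = -sum_mu - 1.0 / sigma**2
            step = np.clip(grad / hess, -5.0, 5.0)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        sum_mu = np.bincount(codes, weights=exp_eta0 * np.exp(b[codes]), minlength=n_groups)
        tau = 1.0 / np.sqrt(sum_mu + 1.0 / sigma**2)

        bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (G, Q)
        # sum over observations of exp(eta0 + b_k), per group and node
        sum_exp = np.empty_like(bk)
        for q in range(nodes.size):
            sum_exp[:, q] = np.bincount(
                codes, weights=exp_eta0 * np.exp(bk[codes, q]), minlength=n_groups
            )
        h = sum_y[:, None] * bk - sum_exp - 0.5 * (bk / sigma) ** 2
        log_terms = np.log(weights)[None, :] + nodes[None, :] ** 2 + h
        per_group = (
            -0.5 * np.log(2.0 * np.pi * sigma**2)
            + np.log(np.sqrt(2.0) * tau)
            + logsumexp(log_terms, axis=1)
        )
        return const + float(np.sum(per_group))

    # ---- fitting --------------------------------------------------------

    def fit(self, X, y, groups, offset=None, exog_names=None):
        """Fit by maximum marginal likelihood.

        Parameters
        ----------
        X : ndarray (n_obs, n_fixed)
            Fixed-effect design matrix (include the intercept column).
        y : ndarray (n_obs,)
            Non-negative integer counts.
        groups : array-like (n_obs,)
            Random-intercept grouping labels (e.g. subject IDs).
        offset : ndarray (n_obs,), optional
            Log-exposure offset (e.g. log analysed minutes).
        exog_names : list of str, optional
            Names for the fixed-effect columns.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        offset = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)
        groups = np.asarray(groups)
        labels, codes = np.unique(groups, return_inverse=True)
        nodes, weights = hermgauss(self.n_quad)

        # starting values from a plain Poisson GLM (no random effect)
        beta0, _ = _poisson_glm(X, y, offset)
        x0 = np.concatenate([beta0, [np.log(0.1)]])

        def neg(params):
            return -self._loglik(params, X, y, codes, labels.size, offset, nodes, weights)

        bounds = [(None, None)] * X.shape[1] + [(np.log(self.sigma_floor), 5.0)]
        res = scipy.optimize.minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        self.converged_ = bool(res.success)
        params = res.x
        self.loglik_ = -float(res.fun)
        self.coef_ = params[:-1].copy()
        self.sigma_ = float(np.exp(params[-1]))
        self.n_obs_ = int(y.size)
        self.n_groups_ = int(labels.size)
        self.n_params_ = X.shape[1] + 1
        self.bic_ = -2.0 * self.loglik_ + self.n_params_ * np.log(self.n_obs_)
        self.exog_names_ = (
            list(exog_names) if exog_names is not None else [f"x{i}" for i in range(X.shape[1])]
        )

        cov = _fd_covariance(neg, params)
        self.params_cov_ = cov
        self.coef_se_ = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))
        # stash the data for simulation / refits
        self._X, self._y, self._offset = X, y, offset
        self._groups, self._codes, self._labels = groups, codes, labels
        return self

    # ---- post-fit utilities ---------------------------------------------

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a new response vector from the fitted model."""
        b = rng.normal(0.0, self.sigma_, self.n_groups_)
        code_of = {lab: i for i, lab in enumerate(self._labels)}
        codes = np.array([code_of[g] for g in self._groups])
        eta = self._X @ self.coef_ + self._offset + b[codes]
        return rng.poisson(np.exp(eta)).astype(float)

    def refit(self, y_new: np.ndarray) -> "PoissonMixedGLM":
        """Fit an identically specified model to a new response."""
        clone = PoissonMixedGLM(
            n_quad=self.n_quad, sigma_floor=self.sigma_floor, maxiter=self.maxiter
        )
        return clone.fit(
            self._X, y_new, self._groups, offset=self._offset, exog_names=self.exog_names_
        )

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float, float]:
        """(estimate, lo, hi) Wald interval for a named coefficient."""
        from scipy.stats import norm

        i = self.exog_names_.index(name)
        z = norm.ppf(0.5 + level / 2.0)
        est, se = self.coef_[i], self.coef_se_[i]
        return float(est), float(est - z * se), float(est + z * se)


def _poisson_glm(X, y, offset):
    """Plain Poisson GLM by IRLS; returns (beta, loglik)."""
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    try:
        res = model.fit()
        return np.asarray(res.params), float(res.llf)
    except Exception:
        return np.zeros(X.shape[1]), -np.inf


def _fd_covariance(neg_loglik, params, eps: float = 1e-4) -> np.ndarray:
    """Covariance from a central finite-difference Hessian of -loglik."""
    p = params.size
    hess = np.zeros((p, p))
    f0 = neg_loglik(params)
    steps = eps * np.maximum(np.abs(params), 1.0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                f_pp = neg_loglik(params + ei)
                f_mm = neg_loglik(params - ei)
                hess[i, i] = (f_pp - 2.0 * f0 + f_mm) / steps[i] ** 2
            else:
                f_pp = neg_loglik(params + ei + ej)
                f_pm = neg_loglik(params + ei - ej)
                f_mp = neg_loglik(params - ei + ej)
                f_mm = neg_loglik(params - ei - ej)
                hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (
                    4.0 * steps[i] * steps[j]
                )
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
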