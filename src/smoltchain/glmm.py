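"""Binomial-logit GLMM with a single random intercept, fitted by marginal ML.

The model for grouped binomial counts (here: survivors among smolts, grouped
by migration year) is

    y_i ~ Binomial(n_i, p_i),   logit(p_i) = x_i' beta + u_{g(i)},
    u_g ~ Normal(0, sigma^2)  independent across groups.

The marginal log-likelihood integrates the random intercept out of each
group's contribution with adaptive Gauss-Hermite quadrature: the integrand is
re-centered at its mode (found by Newton steps) and scaled by the Laplace
curvature before applying the quadrature rule, which keeps the rule accurate
even for the enormous counts of raw fish data.  (beta, log sigma) is then
maximized with a quasi-Newton optimizer.  As sigma -> 0 the marginal
likelihood converges to the ordinary binomial GLM likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats


def _group_modes(eta0, y, n, g_idx, n_groups, sigma2):
    """Vectorized Newton modes and curvatures, per group, of
    loglik_g(u) - u^2/(2 sigma^2)."""
    u = np.zeros(n_groups)
    for _ in range(80):
        p = special.expit(eta0 + u[g_idx])
        grad = np.bincount(g_idx, weights=y - n * p,
                           minlength=n_groups) - u / sigma2
        hess = -np.bincount(g_idx, weights=n * p * (1 - p),
                            minlength=n_groups) - 1.0 / sigma2
        # damp huge steps; counts can be ~1e7 so curvature is extreme
        step = np.clip(-grad / hess, -5.0, 5.0)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(eta0 + u[g_idx])
    hess = -np.bincount(g_idx, weights=n * p * (1 - p),
                        minlength=n_groups) - 1.0 / sigma2
    return u, hess


def marginal_loglik(beta: np.ndarray, log_sigma: float, X: np.ndarray,
                    y: np.ndarray, n: np.ndarray, groups: np.ndarray,
                    n_points: int = 15) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (with binomial
    combinatorial constants, so values are comparable to GLM ``llf``)."""
    sigma = float(np.exp(log_sigma))
    sigma2 = sigma * sigma
    _, g_idx = np.unique(groups, return_inverse=True)
    n_groups = g_idx.max() + 1
    eta0 = X @ beta
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    # hermegauss integrates g(z) against exp(-z^2/2); the Gaussian factor is
    # carried explicitly in the integrand below, so raw weights are used
    logw = np.log(weights)
    const = float(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                         - special.gammaln(n - y + 1)))
    u_hat, hess = _group_modes(eta0, y, n, g_idx, n_groups, sigma2)
    tau = 1.0 / np.sqrt(-hess)                       # Laplace scales, (G,)
    u_nodes = u_hat[:, None] + tau[:, None] * nodes  # (G, n_points)
    eta = eta0[:, None] + u_nodes[g_idx]             # (n_obs, n_points)
    ll_obs = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    ll_grp = np.zeros((n_groups, n_points))
    np.add.at(ll_grp, g_idx, ll_obs)
    # integrand: exp(loglik(u)) * phi(u; 0, sigma); the substitution
    # u = u_hat + tau z gives the adaptive rule with weight correction
    log_integrand = (ll_grp + stats.norm.logpdf(u_nodes, scale=sigma)
                     + 0.5 * nodes[None, :] ** 2 + np.log(tau)[:, None]
                     + logw[None, :])
    return const + float(np.sum(special.logsumexp(log_integrand, axis=1)))


def observed_information(beta: np.ndarray, log_sigma: float, X: np.ndarray,
                         y: np.ndarray, n: np.ndarray, groups: np.ndarray,
                         n_points: int = 15) -> np.ndarray:
    """Observed information of (beta, log sigma) for the marginal likelihood.

    Uses the missing-information identity: the complete-data score and
    curvature are averaged over each group's posterior of the random
    intercept (evaluated on the adaptive quadrature nodes), and the posterior
    variance of the score is subtracted.
    """
    sigma = float(np.exp(log_sigma))
    sigma2 = sigma * sigma
    _, g_idx = np.unique(groups, return_inverse=True)
    G = g_idx.max() + 1
    p = X.shape[1]
    eta0 = X @ beta
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    u_hat, hess = _group_modes(eta0, y, n, g_idx, G, sigma2)
    tau = 1.0 / np.sqrt(-hess)
    u_nodes = u_hat[:, None] + tau[:, None] * nodes        # (G, J)
    eta = eta0[:, None] + u_nodes[g_idx]                   # (n_obs, J)
    ll_obs = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    ll_grp = np.zeros((G, n_points))
    np.add.at(ll_grp, g_idx, ll_obs)
    log_int = (ll_grp + stats.norm.logpdf(u_nodes, scale=sigma)
               + 0.5 * nodes[None, :] ** 2 + np.log(tau)[:, None]
               + np.log(weights)[None, :])
    W = np.exp(log_int - special.logsumexp(log_int, axis=1, keepdims=True))

    prob = special.expit(eta)                              # (n_obs, J)
    resid = y[:, None] - n[:, None] * prob
    info_w = n[:, None] * prob * (1 - prob)
    # complete-data score per group/node, stacked as (G, J, p+1)
    s = np.zeros((G, n_points, p + 1))
    np.add.at(s[:, :, :p], g_idx, resid[:, :, None] * X[:, None, :])
    s[:, :, p] = u_nodes ** 2 / sigma2 - 1.0
    # complete-data curvature (expected part), (G, J, p+1, p+1)
    d2 = np.zeros((G, n_points, p + 1, p + 1))
    np.add.at(d2[:, :, :p, :p], g_idx,
              -info_w[:, :, None, None] * (X[:, None, :, None]
                                           * X[:, None, None, :]))
    d2[:, :, p, p] = -2.0 * u_nodes ** 2 / sigma2
    S_g = np.einsum("gj,gjk->gk", W, s)
    E2_g = np.einsum("gj,gjkl->gkl", W, d2)
    EsS_g = np.einsum("gj,gjk,gjl->gkl", W, s, s)
    cov_g = EsS_g - np.einsum("gk,gl->gkl", S_g, S_g)
    return -(E2_g + cov_g).sum(axis=0)


@dataclass
class GLMMFit:
    """ML fit of the random-intercept binomial GLMM."""

    beta: np.ndarray
    sigma: float
    loglik: float
    cov_beta: np.ndarray          # observed-information covariance of beta
    nobs: int
    n_groups: int
    converged: bool
    term_names: list[str]

    @property
    def sigma2(self) -> float:
        return self.sigma ** 2

    @property
    def k_params(self) -> int:
        return len(self.beta) + 1

    @property
    def aic(self) -> float:
        return -2 * self.loglik + 2 * self.k_params

    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def beta_p(self) -> np.ndarray:
        z = self.beta / self.beta_se()
        return 2 * stats.norm.sf(np.abs(z))

    def predict_prob(self, X: np.ndarray, u: float = 0.0) -> np.ndarray:
        """Survival probability at covariates X with the random intercept
        fixed at u (0 = population-typical year)."""
        return special.expit(np.asarray(X, float) @ self.beta + u)


def fit_binomial_glmm(X: np.ndarray, y: np.ndarray, n: np.ndarray,
                      groups: np.ndarray, term_names: list[str] | None = None,
                      n_points: int = 15, start_beta: np.ndarray | None = None
                      ) -> GLMMFit:
    """Fit the random-intercept binomial GLMM by marginal maximum likelihood.

    Parameters
    ----------
    X : (n_obs, p) design matrix including the intercept column.
    y, n : success and trial counts per observation.
    groups : group label per observation (the random-intercept factor).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    groups = np.asarray(groups)
    p = X.shape[1]

    # standardize non-intercept columns internally: raw-count binomial
    # likelihoods are razor-sharp and badly conditioned in native units
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if start_beta is None:
        import statsmodels.api as sm
        glm = sm.GLM(np.column_stack([y, n - y]), Xs,
                     family=sm.families.Binomial()).fit(maxiter=300,
                                                        tol=1e-6)
        start_beta_s = np.asarray(glm.params, float)
    else:
        start_beta_s = np.asarray(start_beta, float) * sd
        start_beta_s[0] = start_beta[0] + float(start_beta[1:] @ mu[1:])
    def nll(theta):
        log_sigma = np.clip(theta[p], -8.0, 5.0)  # keep sigma^2 positive
        val = marginal_loglik(theta[:p], log_sigma, Xs, y, n, groups,
                              n_points)
        return -val if np.isfinite(val) else 1e12

    best = None
    for ls0 in (np.log(0.5), np.log(1.5)):
        theta0 = np.concatenate([start_beta_s, [ls0]])
        r = optimize.minimize(nll, theta0, method="Nelder-Mead",
                              options={"xatol": 1e-9, "fatol": 1e-9,
                                       "maxiter": 6000, "adaptive": True})
        if best is None or r.fun < best.fun:
            best = r
    res = best
    res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-10,
                                      "maxiter": 4000})
    theta = res2.x if res2.fun <= res.fun else res.x
    fun = min(res.fun, res2.fun)
    if not np.isfinite(fun):
        raise RuntimeError("GLMM optimization failed: non-finite likelihood")
    # exact observed information (missing-information identity), then the
    # beta block of its inverse
    info = observed_information(theta[:p], float(np.clip(theta[p], -8., 5.)),
                                Xs, y, n, groups, n_points)
    try:
        cov_full = np.linalg.inv(info)
        cov_s = cov_full[:p, :p]
        if np.any(np.diag(cov_s) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_s = np.full((p, p), np.nan)
    # back-transform estimates and covariance to native units
    J = np.diag(1.0 / sd)
    J[0, 1:] = -mu[1:] / sd[1:]
    beta = J @ theta[:p]
    cov = J @ cov_s @ J.T
    names = term_names or [f"x{i}" for i in range(p)]
    return GLMMFit(beta, float(np.exp(np.clip(theta[p], -8.0, 5.0))),
                   -fun, cov,
                   len(y), len(np.unique(groups)), bool(res.success or
                                                        res2.success), names)


def binomial_saturated_loglik(y: np.ndarray, n: np.ndarray) -> float:
    """Log-likelihood of the saturated binomial model (p_i = y_i/n_i)."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / n), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log1p(-y / n), 0.0)
    const = np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                   - special.gammaln(n - y + 1))
    return float(np.sum(t1 + t2) + const)
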