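"""Penalized cubic regression spline with GCV smoothness selection.

A single univariate smooth f(x) alongside optional unpenalized linear terms:

    y = alpha + Z*gamma + B(x)*beta + eps,   eps ~ N(0, sigma^2)

B is a cubic B-spline basis (default dimension 10) with knots at quantiles
of x, reparameterized into the null space of the sum-to-zero constraint
(sum_i f(x_i) = 0) so the smooth is identifiable next to the intercept.
Wiggliness is penalized by the integrated squared second derivative of f
(the cubic-spline curvature penalty, whose null space is the straight
lines); the penalty weight lambda minimizes the generalized
cross-validation score GCV = n*RSS / (n - tr(H))^2.

The effective degrees of freedom of the smooth (trace of the influence matrix
over the spline block) and an approximate F-test p-value for the smooth term
are reported, following standard GAM practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3
                    ) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree,
                                 extrapolate=True).toarray()


def _curvature_penalty(knots: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Exact integral of B_i''(x) B_j''(x): the cubic-spline wiggliness
    penalty.  Its null space contains all straight lines, so infinite
    smoothing recovers the ordinary linear fit.  Second derivatives of a
    cubic B-spline are piecewise linear, so 2-point Gauss-Legendre per
    inter-knot interval integrates the products exactly."""
    basis = BSpline(knots, np.eye(k), degree)
    breaks = np.unique(knots)
    g = np.array([-1.0, 1.0]) / np.sqrt(3.0)     # 2-point Gauss nodes
    S = np.zeros((k, k))
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        half = 0.5 * (b - a)
        xs = 0.5 * (a + b) + half * g
        D2 = basis(xs, 2)                        # (2, k)
        S += half * (D2.T @ D2)                  # equal unit weights
    return S


@dataclass
class PenalizedSplineFit:
    """Fitted smooth-plus-linear Gaussian model."""

    coef: np.ndarray              # [intercept, linear terms..., spline coefs]
    n_linear: int
    knots: np.ndarray
    degree: int
    constraint_Z: np.ndarray      # (k, k-1) null-space basis of the constraint
    lam: float
    edf_smooth: float
    edf_total: float
    rss: float
    nobs: int
    cov: np.ndarray               # Bayesian posterior covariance of coef
    gcv: float
    smooth_p: float               # approximate F-test p-value of the smooth
    linear_p: np.ndarray          # two-sided p-values of linear terms

    @property
    def sigma2(self) -> float:
        return self.rss / self.nobs

    @property
    def loglik(self) -> float:
        n = self.nobs
        return -0.5 * n * (np.log(2 * np.pi * self.sigma2) + 1)

    @property
    def aic(self) -> float:
        """Likelihood-scale AIC with k = total edf + 1 (scale)."""
        return -2 * self.loglik + 2 * (self.edf_total + 1)

    def _design(self, x: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
        B = _bspline_design(np.asarray(x, float), self.knots, self.degree)
        Bz = B @ self.constraint_Z
        cols = [np.ones((len(x), 1))]
        if self.n_linear:
            cols.append(np.asarray(Z, float).reshape(len(x), self.n_linear))
        cols.append(Bz)
        return np.hstack(cols)

    def predict(self, x, Z=None) -> np.ndarray:
        return self._design(np.asarray(x, float), Z) @ self.coef

    def smooth_effect(self, x) -> np.ndarray:
        """Centered partial effect of the smooth term at new x."""
        B = _bspline_design(np.asarray(x, float), self.knots, self.degree)
        return B @ self.constraint_Z @ self.coef[1 + self.n_linear:]


def fit_pspline(x, y, Z=None, k: int = 10, degree: int = 3,
                loglam_bounds: tuple[float, float] = (-6.0, 12.0)
                ) -> PenalizedSplineFit:
    """Fit the penalized spline model, selecting lambda by GCV.

    Parameters
    ----------
    x : array
        Covariate entering the smooth.
    y : array
        Gaussian response.
    Z : array or None
        Optional (n, q) matrix of unpenalized linear covariates.
    k : int
        Spline basis dimension before centering (default 10).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for k={k}")
    Z = None if Z is None else np.asarray(Z, float).reshape(n, -1)
    q = 0 if Z is None else Z.shape[1]

    # knots: quantile-spaced interior knots, clamped boundary
    n_interior = k - degree - 1
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, probs) if n_interior > 0 else np.array([])
    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1e-8)
    knots = np.concatenate([np.full(degree + 1, lo - 1e-8 * span),
                            np.sort(interior),
                            np.full(degree + 1, hi + 1e-8 * span)])
    B = _bspline_design(x, knots, degree)
    # sum-to-zero constraint: project the basis onto the null space of its
    # column sums (partition of unity makes the raw basis collinear with the
    # intercept)
    C = B.sum(axis=0).reshape(-1, 1)
    Qc, _ = np.linalg.qr(C, mode="complete")
    Zc = Qc[:, 1:]                               # (k, k-1)
    Bz = B @ Zc
    ks = k - 1                                   # spline block size

    cols = [np.ones((n, 1))]
    if q:
        cols.append(Z)
    X = np.hstack(cols + [Bz])
    p = X.shape[1]
    S = np.zeros((p, p))
    S[-ks:, -ks:] = Zc.T @ _curvature_penalty(knots, k, degree) @ Zc
    # scale-free penalty normalization so loglam bounds are portable
    S *= np.trace(X.T @ X) / max(np.trace(S), 1e-300)

    XtX = X.T @ X
    Xty = X.T @ y

    def fit_at(lam: float):
        A = XtX + lam * S
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)   # extreme lambda: rank-safe fallback
        coef = Ainv @ Xty
        H_tr_blocks = Ainv @ XtX                 # influence on coefficients
        edf_total = float(np.trace(H_tr_blocks))
        edf_smooth = float(np.trace(H_tr_blocks[-ks:, -ks:]))
        resid = y - X @ coef
        rss = float(resid @ resid)
        denom = max(n - edf_total, 1e-8)
        gcv = n * rss / denom ** 2
        return coef, Ainv, edf_total, edf_smooth, rss, gcv

    def gcv_of(loglam: float) -> float:
        return fit_at(10.0 ** loglam)[-1]

    grid = np.linspace(*loglam_bounds, 25)
    g0 = min(grid, key=gcv_of)
    res = optimize.minimize_scalar(
        gcv_of, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-4})
    if not np.isfinite(res.fun):
        raise RuntimeError("GCV surface non-finite near its grid minimum")
    lam = 10.0 ** float(res.x)
    coef, Ainv, edf_total, edf_smooth, rss, gcv = fit_at(lam)
    sigma2 = rss / max(n - edf_total, 1e-8)
    cov = sigma2 * Ainv                          # Bayesian posterior cov

    # smooth-term test: rank-r Wald statistic on the fitted smooth values,
    # using the top-r eigenspace of their posterior covariance with
    # r = edf rounded up (the standard test for penalized smooths, which
    # accounts for the penalty unlike a naive RSS-difference F test)
    f_hat = Bz @ coef[-ks:]
    V_f = Bz @ cov[-ks:, -ks:] @ Bz.T
    r = int(min(np.ceil(edf_smooth), ks))
    evals, evecs = np.linalg.eigh(V_f)
    order = np.argsort(evals)[::-1][:r]
    proj = evecs[:, order].T @ f_hat
    lam_r = np.maximum(evals[order], 1e-300)
    tr_stat = float(np.sum(proj ** 2 / lam_r))
    smooth_p = float(stats.f.sf(tr_stat / r, r, max(n - edf_total, 1)))

    lin_p = np.empty(q)
    for j in range(q):
        se = np.sqrt(cov[1 + j, 1 + j])
        tstat = coef[1 + j] / se if se > 0 else np.inf
        lin_p[j] = 2 * stats.t.sf(abs(tstat), max(n - edf_total, 1))

    return PenalizedSplineFit(coef, q, knots, degree, Zc, lam,
                              edf_smooth, edf_total, rss, n, cov, gcv,
                              smooth_p, lin_p)
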