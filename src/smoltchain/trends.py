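"""Directional-trend testing with paired OLS and GLS-AR(1) fits.

Every annual series is regressed on calendar (or brood) year twice: by
ordinary least squares, and by generalized least squares with first-order
autoregressive errors ``e_t = rho * e_{t-1} + eta_t`` fitted by full maximum
likelihood.  Because both models share the mean structure and are fitted by
ML, a likelihood-ratio test on 1 df arbitrates between them; the AR(1) model
is preferred when the test rejects at the (configurable) 0.05 level.

Gaps in the year lattice are handled through the Markov property of the
stationary AR(1) process: across a gap of g years the correlation decays to
``rho**g``, giving an exact O(n) likelihood by sequential whitening.

Proportion-kind series are arcsine-square-root transformed before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from smoltchain.tsio import (AnnualSeries, BiologicalTable,
                             EnvironmentalTable, arcsin_sqrt)


@dataclass
class OLSTrend:
    slope: float
    intercept: float
    ci: tuple[float, float]
    r2: float
    p_value: float
    loglik: float
    nobs: int
    degenerate: bool = False


@dataclass
class GLSTrend:
    slope: float
    intercept: float
    ci: tuple[float, float]
    rho: float
    p_value: float
    loglik: float
    nobs: int


@dataclass
class TrendResult:
    name: str
    ols: OLSTrend
    gls: GLSTrend
    lrt_stat: float
    lrt_p: float
    preferred: str            # "OLS" or "GLS"

    @property
    def preferred_p(self) -> float:
        return self.gls.p_value if self.preferred == "GLS" else self.ols.p_value


def _prepare(series: AnnualSeries) -> tuple[np.ndarray, np.ndarray]:
    s = series.dropna()
    if len(s) < 5:
        raise ValueError(f"{series.name}: fewer than 5 observed years")
    y = s.values
    if series.kind == "proportion":
        y = arcsin_sqrt(y)
    return s.years.astype(float), y


def fit_ols_trend(series: AnnualSeries) -> OLSTrend:
    """OLS slope of the series on year, with 95% CI, R^2 and two-sided p.

    The log-likelihood is the Gaussian ML value (variance estimated by /n) so
    it is directly comparable with the AR(1) ML fit.  A constant series is
    flagged degenerate with slope 0 and p = 1.
    """
    t, y = _prepare(series)
    n = len(y)
    if np.ptp(y) == 0:
        ll = np.inf  # zero residual variance; LRT vs GLS is meaningless
        return OLSTrend(0.0, float(y[0]), (0.0, 0.0), 0.0, 1.0, ll, n,
                        degenerate=True)
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    sigma2 = float(resid @ resid) / n
    if sigma2 < 1e-300:
        # exact linear series: zero residual variance, AR(1) arbitration moot
        return OLSTrend(float(res.slope), float(res.intercept),
                        (float(res.slope), float(res.slope)), 1.0, 0.0,
                        np.inf, n, degenerate=True)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    tq = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    return OLSTrend(float(res.slope), float(res.intercept),
                    (float(ci[0]), float(ci[1])), float(res.rvalue ** 2),
                    float(res.pvalue), ll, n)


def _ar1_whiten(t: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Whitening lag-weights and innovation variances for an AR(1) on an
    integer lattice with gaps.  Returns (lagcoef, v) where row i of a series
    is whitened as (y_i - lagcoef_i * y_{i-1}) / sqrt(v_i)."""
    gaps = np.diff(t)
    lag = np.concatenate([[0.0], rho ** gaps])
    v = np.concatenate([[1.0], 1.0 - rho ** (2 * gaps)])
    return lag, v


def _ar1_profile_loglik(rho: float, t: np.ndarray, y: np.ndarray
                        ) -> tuple[float, np.ndarray, float]:
    """Profile ML log-likelihood of the linear-trend AR(1) model at rho.

    beta and the marginal error variance are profiled out analytically on the
    whitened data.  Returns (loglik, beta_hat, sigma_e2_hat)."""
    n = len(y)
    X = np.column_stack([np.ones(n), t])
    lag, v = _ar1_whiten(t, rho)
    sq = np.sqrt(v)
    Xw = (X - lag[:, None] * np.vstack([np.zeros(2), X[:-1]])) / sq[:, None]
    yw = (y - lag * np.concatenate([[0.0], y[:-1]])) / sq
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma_e2 = rss / n
    if sigma_e2 <= 0:
        return np.inf, beta, 0.0
    ll = (-0.5 * n * (np.log(2 * np.pi * sigma_e2) + 1)
          - 0.5 * float(np.sum(np.log(v))))
    return ll, beta, sigma_e2


def fit_gls_ar1_trend(series: AnnualSeries,
                      rho_bound: float = 0.99) -> GLSTrend:
    """Maximum-likelihood GLS trend with AR(1) errors.

    rho is profiled over (-rho_bound, rho_bound) by bounded scalar
    optimization of the exact likelihood; the slope CI uses the whitened-
    design covariance at the ML estimates with a t(n-2) quantile.
    """
    t, y = _prepare(series)
    n = len(y)
    res = optimize.minimize_scalar(
        lambda r: -_ar1_profile_loglik(r, t, y)[0],
        bounds=(-rho_bound, rho_bound), method="bounded",
        options={"xatol": 1e-7})
    rho = float(res.x)
    ll, beta, sigma_e2 = _ar1_profile_loglik(rho, t, y)
    if not np.isfinite(ll):
        raise RuntimeError(f"{series.name}: AR(1) likelihood non-finite "
                           f"at rho={rho:.4f}")
    lag, v = _ar1_whiten(t, rho)
    sq = np.sqrt(v)
    X = np.column_stack([np.ones(n), t])
    Xw = (X - lag[:, None] * np.vstack([np.zeros(2), X[:-1]])) / sq[:, None]
    # small-sample variance with the usual n-p correction
    sigma2_c = sigma_e2 * n / max(n - 2, 1)
    cov = sigma2_c * np.linalg.inv(Xw.T @ Xw)
    se = float(np.sqrt(cov[1, 1]))
    tq = stats.t.ppf(0.975, n - 2)
    tstat = beta[1] / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return GLSTrend(float(beta[1]), float(beta[0]),
                    (float(beta[1] - tq * se), float(beta[1] + tq * se)),
                    rho, p, ll, n)


def lrt_compare(ols: OLSTrend, gls: GLSTrend) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value for AR(1) errors vs iid.

    Both fits must be ML on the same data with the same mean structure.  The
    statistic 2*(l_GLS - l_OLS) is referred to chi-square with 1 df.  A
    statistic below -1e-6 signals a failed optimization and raises.
    """
    if ols.nobs != gls.nobs:
        raise ValueError("LRT requires fits on identical data")
    stat = 2.0 * (gls.loglik - ols.loglik)
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic {stat:.3g}: "
                           "AR(1) optimization failed to dominate OLS")
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def fit_trend(series: AnnualSeries, lrt_alpha: float = 0.05) -> TrendResult:
    """Paired OLS / GLS-AR(1) fit with likelihood-ratio arbitration."""
    ols = fit_ols_trend(series)
    if ols.degenerate:
        # constant (slope 0, p 1) or exact-linear (R^2 1, p 0) series:
        # the AR(1) error model has nothing to fit
        gls = GLSTrend(ols.slope, ols.intercept, ols.ci, 0.0,
                       ols.p_value, ols.loglik, ols.nobs)
        return TrendResult(series.name, ols, gls, 0.0, 1.0, "OLS")
    gls = fit_gls_ar1_trend(series)
    stat, p = lrt_compare(ols, gls)
    preferred = "GLS" if p < lrt_alpha else "OLS"
    return TrendResult(series.name, ols, gls, stat, p, preferred)


def default_catalog(bio: BiologicalTable | None = None,
                    env: EnvironmentalTable | None = None,
                    productivity: pd.DataFrame | None = None
                    ) -> dict[str, AnnualSeries]:
    """Assemble the standard trend catalog from the available tables.

    Environmental entries: the twelve monthly air-temperature means, derived
    seasonal covariates, June water temperature, ice-out date and the marine
    climate indices.  Biological entries: abundances, productivity metrics,
    age-composition proportions, growth indices and migration phenology.
    """
    cat: dict[str, AnnualSeries] = {}
    if env is not None:
        from smoltchain.tsio import MARINE_INDEX_COLS, MONTH_COLS
        for c in MONTH_COLS:
            cat[c] = env.series(c, "temperature")
        for c in ["spring_mean", "autumn_mean", "spawning_mean_high",
                  "winter_mean_low", "degree_days", "h2o_june_c"]:
            cat[c] = env.series(c, "temperature")
        cat["iceout_doy"] = env.series("iceout_doy", "phenology")
        for c in MARINE_INDEX_COLS:
            cat[c] = env.series(c, "index")
    if bio is not None:
        for c in ["escapement", "r12", "r13", "r22", "r23",
                  "n_smolt1", "n_smolt2"]:
            cat[c] = bio.series(c, "abundance")
        for c in ["len_smolt1_mm", "len_smolt2_mm",
                  "wt_smolt1_g", "wt_smolt2_g", "fry_len_mm"]:
            cat[c] = bio.series(c, "growth")
        cat["smolt_median_doy"] = bio.series("smolt_median_doy", "phenology")
    if productivity is not None:
        for c, kind in [("rps", "productivity"), ("rps_index", "productivity"),
                        ("sps", "productivity"), ("sas", "proportion"),
                        ("p_fw1", "proportion"), ("p_oc2", "proportion"),
                        ("p_smolt1", "proportion")]:
            sub = productivity[["brood_year", c]].dropna()
            if len(sub) >= 5:
                cat[c] = AnnualSeries(c, sub["brood_year"].to_numpy(int),
                                      sub[c].to_numpy(float), kind,
                                      axis="brood_year")
    return cat


def trend_table(catalog: dict[str, AnnualSeries], alpha: float = 0.1,
                lrt_alpha: float = 0.05) -> pd.DataFrame:
    """Fit the paired trend models for every catalog entry.

    Returns one row per variable with OLS and GLS estimates, rho, the LRT
    p-value, the preferred model tag and a significance flag at ``alpha``
    (evaluated on the preferred model's slope p-value).  Unresolvable or
    too-short series are listed with status 'skipped'.
    """
    rows = []
    for name, series in catalog.items():
        try:
            r = fit_trend(series, lrt_alpha)
        except (ValueError, RuntimeError) as exc:
            rows.append({"variable": name, "status": f"skipped: {exc}"})
            continue
        rows.append({
            "variable": name, "status": "ok", "n": r.ols.nobs,
            "ols_slope": r.ols.slope, "ols_lo": r.ols.ci[0],
            "ols_hi": r.ols.ci[1], "r2": r.ols.r2, "ols_p": r.ols.p_value,
            "gls_slope": r.gls.slope, "gls_lo": r.gls.ci[0],
            "gls_hi": r.gls.ci[1], "rho": r.gls.rho, "gls_p": r.gls.p_value,
            "lrt_p": r.lrt_p, "preferred": r.preferred,
            "significant": bool(r.preferred_p < alpha),
        })
    return pd.DataFrame(rows)
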