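"""Intermediate-relationship model catalogs with AIC multimodel inference.

Five catalogs chain freshwater climate to salmon productivity:

FL   fry length (1 Sep) ~ spring temperature (linear or penalized-spline
     smooth) + fry density + yearling density            [normal]
AC   proportion of a brood's smolts migrating at age 1 ~ fry length,
     migration-spring temperature, condition, year       [beta, logit link]
SAS  smolt-to-adult survival counts by migration year x freshwater age ~
     smolt age + mean length, with or without a migration-year random
     intercept                                           [binomial, logit]
RS   ln(R/S) ~ standardized SAS and/or smolts-per-spawner, for coefficient
     comparison and deviance partitioning                [lognormal]
DC   ln(R/S) ~ escapement + smooth(spring temperature): the direct
     temperature-productivity check in Ricker form       [lognormal]

Density indices follow standard practice for this system: fry density is the
natural log of the spawning escapement that produced the cohort, and yearling
density the natural log of age-2 smolts migrating the following spring.

Within each catalog every candidate is fitted on the complete cases of the
largest member so AICs are comparable, and Akaike weights
w_i = exp(-0.5 dAIC_i)/sum_j exp(-0.5 dAIC_j) rank the candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from smoltchain import glmm as _glmm
from smoltchain import pspline as _pspline
from smoltchain.broodtable import condition_factor

SMOOTH_PREFIX = "s("


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, terms and error family.

    Terms are column names of the catalog's model frame; a smooth term is
    written ``s(name)``; ``random:group`` adds a random intercept on the
    grouping column (binomial family only).
    """

    id: str
    response: str
    terms: tuple[str, ...]
    family: str                      # normal | beta-logit | binomial-logit | lognormal

    @property
    def smooth_terms(self) -> list[str]:
        return [t[2:-1] for t in self.terms if t.startswith(SMOOTH_PREFIX)]

    @property
    def linear_terms(self) -> list[str]:
        return [t for t in self.terms
                if not t.startswith(SMOOTH_PREFIX)
                and not t.startswith("random:")]

    @property
    def random_group(self) -> str | None:
        for t in self.terms:
            if t.startswith("random:"):
                return t.split(":", 1)[1]
        return None

    @property
    def data_columns(self) -> list[str]:
        cols = [self.response] + self.linear_terms + self.smooth_terms
        if self.random_group:
            cols.append(self.random_group)
        return cols


def _specs(defs, response, family):
    return tuple(ModelSpec(i, response, tuple(t), family) for i, t in defs)


FL_CATALOG = _specs([
    ("FL-1", ["spring_temp", "fry", "yearlings"]),
    ("FL-1gam", ["s(spring_temp)", "fry", "yearlings"]),
    ("FL-2", ["spring_temp", "fry_plus_yearlings"]),
    ("FL-2gam", ["s(spring_temp)", "fry_plus_yearlings"]),
    ("FL-3", ["spring_temp", "fry"]),
    ("FL-3gam", ["s(spring_temp)", "fry"]),
    ("FL-4", ["spring_temp", "yearlings"]),
    ("FL-4gam", ["s(spring_temp)", "yearlings"]),
    ("FL-5", ["spring_temp"]),
    ("FL-5gam", ["s(spring_temp)"]),
], "fry_len", "normal")

AC_CATALOG = _specs([
    ("AC-1", ["fry_len", "spring_temp_mig", "year"]),
    ("AC-2", ["fry_len", "condition", "year"]),
    ("AC-3", ["fry_len", "year"]),
    ("AC-4", ["fry_len", "spring_temp_mig"]),
    ("AC-5", ["fry_len", "condition"]),
    ("AC-6", ["fry_len"]),
], "p_smolt1", "beta-logit")

SAS_CATALOG = _specs([
    ("SAS-1", ["length", "age2"]),
    ("SAS-1R", ["length", "age2", "random:migration_year"]),
    ("SAS-2", ["age2"]),
    ("SAS-2R", ["age2", "random:migration_year"]),
    ("SAS-3", ["length"]),
    ("SAS-3R", ["length", "random:migration_year"]),
], "sas", "binomial-logit")

RS_CATALOG = _specs([
    ("RS-1", ["sas_z", "sps_z"]),
    ("RS-2", ["sas_z"]),
    ("RS-3", ["sps_z"]),
], "ln_rps", "lognormal")

DC_CATALOG = _specs([
    ("DC-1", ["escapement", "s(spring_temp)"]),
], "ln_rps", "lognormal")

CATALOGS: dict[str, tuple[ModelSpec, ...]] = {
    "FL": FL_CATALOG, "AC": AC_CATALOG, "SAS": SAS_CATALOG,
    "RS": RS_CATALOG, "DC": DC_CATALOG,
}


@dataclass
class FitResult:
    """One fitted candidate: estimates, likelihood, AIC and deviance share."""

    spec: ModelSpec
    terms: dict[str, dict]            # name -> {estimate, p_value}
    loglik: float
    aic: float
    nobs: int
    pct_deviance: float
    edf_smooth: float | None = None
    re_var: float | None = None       # random-intercept variance (sigma^2)
    aic_weight: float | None = None
    model: object = field(default=None, repr=False)

    @property
    def id(self) -> str:
        return self.spec.id


def aic_weights(fits: list[FitResult]) -> list[FitResult]:
    """Attach Akaike weights; fits must share the same case set."""
    if len({f.nobs for f in fits}) > 1:
        raise ValueError("AIC weights require fits on identical case sets")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.aic_weight = float(wi)
    return fits


def deviance_explained(deviance: float, null_deviance: float) -> float:
    """Percent deviance explained, 100 * (1 - D/D_null)."""
    if null_deviance <= 0:
        raise ValueError("null deviance is zero; deviance share undefined")
    return 100.0 * (1.0 - deviance / null_deviance)


def _pct_dev(deviance: float, null_deviance: float) -> float:
    """Deviance share, NaN-flagged when the null deviance degenerates."""
    if null_deviance <= 1e-12:
        return math.nan
    return deviance_explained(deviance, null_deviance)


# ---------------------------------------------------------------------------
# per-family fitters


def _design(data: pd.DataFrame, terms: list[str]) -> np.ndarray:
    X = data[terms].to_numpy(float) if terms else np.empty((len(data), 0))
    return np.column_stack([np.ones(len(data)), X])


def fit_linear(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Gaussian linear candidate by OLS/ML; AIC counts the scale parameter."""
    y = data[spec.response].to_numpy(float)
    X = _design(data, spec.linear_terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{spec.id}: rank-deficient design "
                         f"({spec.linear_terms})")
    res = sm.OLS(y, X).fit()
    aic = -2 * res.llf + 2 * (X.shape[1] + 1)
    tss = float(np.sum((y - y.mean()) ** 2))
    terms = {name: {"estimate": float(res.params[i + 1]),
                    "p_value": float(res.pvalues[i + 1])}
             for i, name in enumerate(spec.linear_terms)}
    terms["intercept"] = {"estimate": float(res.params[0]),
                          "p_value": float(res.pvalues[0])}
    return FitResult(spec, terms, float(res.llf), float(aic), len(y),
                     deviance_explained(float(res.ssr), tss), model=res)


def fit_gam_pspline(spec: ModelSpec, data: pd.DataFrame, k: int = 10
                    ) -> FitResult:
    """Gaussian candidate with one GCV-selected penalized-spline smooth."""
    (sm_var,) = spec.smooth_terms
    y = data[spec.response].to_numpy(float)
    x = data[sm_var].to_numpy(float)
    Z = (data[spec.linear_terms].to_numpy(float)
         if spec.linear_terms else None)
    fit = _pspline.fit_pspline(x, y, Z=Z, k=k)
    tss = float(np.sum((y - y.mean()) ** 2))
    terms = {f"s({sm_var})": {"estimate": math.nan,
                              "p_value": fit.smooth_p,
                              "edf": fit.edf_smooth}}
    for j, name in enumerate(spec.linear_terms):
        terms[name] = {"estimate": float(fit.coef[1 + j]),
                       "p_value": float(fit.linear_p[j])}
    terms["intercept"] = {"estimate": float(fit.coef[0]), "p_value": math.nan}
    return FitResult(spec, terms, fit.loglik, fit.aic, fit.nobs,
                     deviance_explained(fit.rss, tss),
                     edf_smooth=fit.edf_smooth, model=fit)


def clamp_unit(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 proportions into the open interval by the standard
    (y*(n-1)+0.5)/n adjustment."""
    y = np.asarray(y, float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def _beta_loglik_sat(y: np.ndarray, phi: float) -> float:
    """Saturated beta log-likelihood (mu_i = y_i) at precision phi."""
    a = y * phi
    b = (1 - y) * phi
    return float(np.sum(stats.beta.logpdf(y, a, b)))


def _beta_null_loglik(y: np.ndarray, phi: float) -> float:
    """Intercept-only beta log-likelihood with precision fixed at phi."""

    def nll(mu_logit):
        mu = 1.0 / (1.0 + np.exp(-mu_logit))
        return -np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(nll, bounds=(-10, 10), method="bounded")
    return -float(res.fun)


def fit_beta_logit(spec: ModelSpec, data: pd.DataFrame,
                   clamp: bool = True) -> FitResult:
    """Beta-regression candidate with logit mean link and free precision.

    The response must lie strictly in (0,1); exact 0/1 values raise unless
    ``clamp`` applies the (y*(n-1)+0.5)/n adjustment.  AIC counts the
    precision parameter, so negative AICs are legitimate for well-fitting
    proportion models.  Percent deviance uses D = 2*(l_sat - l) with both
    the saturated and the intercept-only null likelihood evaluated at the
    fitted model's precision, the convention GAM software uses for
    estimated-theta families.
    """
    y = data[spec.response].to_numpy(float)
    if ((y <= 0) | (y >= 1)).any():
        if not clamp:
            raise ValueError(f"{spec.id}: response at 0/1; enable clamping "
                             "(clamp=True) to adjust into (0,1)")
        y = clamp_unit(y)
    X = _design(data, spec.linear_terms)
    p = X.shape[1]
    # standardize predictors for the optimizer; estimates are transformed
    # back to native units afterwards
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    res = BetaModel(y, Xs).fit(disp=False)
    if not res.mle_retvals.get("converged", True):
        # retry from a logit-OLS start with a derivative-free pass first
        start = np.append(np.linalg.lstsq(Xs, np.log(y / (1 - y)),
                                          rcond=None)[0], np.log(20.0))
        res = BetaModel(y, Xs).fit(start_params=start, method="nm",
                                   maxiter=5000, disp=False)
        res = BetaModel(y, Xs).fit(start_params=res.params, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"{spec.id}: beta-regression MLE did not "
                               "converge")
    k = len(res.params)                       # mean coefs + precision
    ll = float(res.llf)
    aic = -2 * ll + 2 * k
    phi = float(np.exp(res.params[-1]))       # log-link precision
    l_sat = _beta_loglik_sat(y, phi)
    dev = 2 * (l_sat - ll)
    dev0 = 2 * (l_sat - _beta_null_loglik(y, phi))
    J = np.diag(1.0 / sd)
    J[0, 1:] = -mu[1:] / sd[1:]
    beta = J @ np.asarray(res.params[:p])
    cov = J @ np.asarray(res.cov_params())[:p, :p] @ J.T
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    terms = {name: {"estimate": float(beta[i + 1]),
                    "p_value": float(pvals[i + 1]),
                    "se": float(se[i + 1])}
             for i, name in enumerate(spec.linear_terms)}
    terms["intercept"] = {"estimate": float(beta[0]),
                          "p_value": float(pvals[0]), "se": float(se[0])}
    terms["phi"] = {"estimate": phi, "p_value": math.nan}
    return FitResult(spec, terms, ll, float(aic), len(y),
                     deviance_explained(dev, dev0), model=res)


def _binomial_counts(spec: ModelSpec, data: pd.DataFrame):
    succ = np.round(data["n_returns"].to_numpy(float)).astype(np.int64)
    trials = np.round(data["n_smolts"].to_numpy(float)).astype(np.int64)
    succ = np.minimum(succ, trials)
    X = _design(data, spec.linear_terms)
    return X, succ, trials


def fit_binomial_glm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fixed-effects binomial-logit candidate on raw fish counts (IRLS)."""
    X, succ, trials = _binomial_counts(spec, data)
    # absolute deviance tolerance: raw fish counts put deviances near 1e9,
    # so the default 1e-8 criterion can never be met in float64
    res = sm.GLM(np.column_stack([succ, trials - succ]), X,
                 family=sm.families.Binomial()).fit(maxiter=300, tol=1e-6)
    if not res.converged:
        raise RuntimeError(f"{spec.id}: IRLS failed to converge")
    aic = -2 * float(res.llf) + 2 * X.shape[1]
    terms = {name: {"estimate": float(res.params[i + 1]),
                    "p_value": float(res.pvalues[i + 1])}
             for i, name in enumerate(spec.linear_terms)}
    terms["intercept"] = {"estimate": float(res.params[0]),
                          "p_value": float(res.pvalues[0])}
    return FitResult(spec, terms, float(res.llf), aic, len(succ),
                     _pct_dev(float(res.deviance),
                              float(res.null_deviance)), model=res)


def fit_binomial_glmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Random-intercept binomial candidate by adaptive Gauss-Hermite ML.

    One intercept per level of the grouping column (migration year); percent
    deviance is computed against the fixed-intercept-only GLM null, so the
    variance soaked up by the year intercepts counts as explained.
    """
    group_col = spec.random_group
    X, succ, trials = _binomial_counts(spec, data)
    groups = data[group_col].to_numpy()
    fit = _glmm.fit_binomial_glmm(X, succ, trials, groups,
                                  term_names=["intercept"] + spec.linear_terms)
    pvals = fit.beta_p()
    terms = {name: {"estimate": float(fit.beta[i + 1]),
                    "p_value": float(pvals[i + 1])}
             for i, name in enumerate(spec.linear_terms)}
    terms["intercept"] = {"estimate": float(fit.beta[0]),
                          "p_value": float(pvals[0])}
    terms["year_var"] = {"estimate": fit.sigma2, "p_value": math.nan}
    l_sat = _glmm.binomial_saturated_loglik(succ, trials)
    dev = 2 * (l_sat - fit.loglik)
    null = sm.GLM(np.column_stack([succ, trials - succ]),
                  np.ones((len(succ), 1)),
                  family=sm.families.Binomial()).fit(maxiter=300, tol=1e-6)
    dev0 = 2 * (l_sat - float(null.llf))
    return FitResult(spec, terms, fit.loglik, fit.aic, len(succ),
                     _pct_dev(dev, dev0), re_var=fit.sigma2,
                     model=fit)


_FITTERS = {
    "normal": fit_linear, "lognormal": fit_linear,
    "beta-logit": fit_beta_logit, "binomial-logit": fit_binomial_glm,
}


def fit_model(spec: ModelSpec, data: pd.DataFrame, k: int = 10,
              clamp: bool = True) -> FitResult:
    """Dispatch a candidate to its family fitter."""
    if spec.smooth_terms:
        if spec.family not in ("normal", "lognormal"):
            raise ValueError("smooth terms supported in Gaussian families only")
        return fit_gam_pspline(spec, data, k=k)
    if spec.random_group:
        if spec.family != "binomial-logit":
            raise ValueError("random intercepts supported in binomial only")
        return fit_binomial_glmm(spec, data)
    if spec.family == "beta-logit":
        return fit_beta_logit(spec, data, clamp=clamp)
    return _FITTERS[spec.family](spec, data)


@dataclass
class CatalogResult:
    catalog_id: str
    fits: list[FitResult]
    failed: dict[str, str]
    data: pd.DataFrame

    def best(self) -> FitResult:
        return max(self.fits, key=lambda f: f.aic_weight)

    def report(self) -> pd.DataFrame:
        rows = []
        for f in sorted(self.fits, key=lambda g: g.aic):
            for name, t in f.terms.items():
                rows.append({"model_id": f.id, "term": name,
                             "estimate": t["estimate"],
                             "p_value": t["p_value"], "aic": f.aic,
                             "aic_weight": f.aic_weight,
                             "pct_deviance": f.pct_deviance})
        for mid, msg in self.failed.items():
            rows.append({"model_id": mid, "term": f"FAILED: {msg}",
                         "estimate": np.nan, "p_value": np.nan,
                         "aic": np.nan, "aic_weight": np.nan,
                         "pct_deviance": np.nan})
        return pd.DataFrame(rows)


def run_catalog(catalog_id: str, frame: pd.DataFrame,
                specs: tuple[ModelSpec, ...] | None = None,
                **kw) -> CatalogResult:
    """Fit every candidate of a catalog on the common complete-case set.

    Complete cases are those of the union of all candidates' columns, so the
    AICs (and weights) are comparable across the catalog.  A candidate whose
    fit raises is reported as failed; the others proceed.
    """
    if specs is None:
        specs = CATALOGS[catalog_id]
    cols: list[str] = []
    for s in specs:
        cols.extend(c for c in s.data_columns if c not in cols)
    if catalog_id == "SAS":
        cols.extend(c for c in ("n_returns", "n_smolts") if c not in cols)
    data = frame.dropna(subset=[c for c in cols if c in frame.columns])
    data = data.reset_index(drop=True)
    fits, failed = [], {}
    for s in specs:
        try:
            fits.append(fit_model(s, data, **kw))
        except (ValueError, KeyError, RuntimeError,
                np.linalg.LinAlgError) as exc:
            failed[s.id] = str(exc)
    if fits:
        aic_weights(fits)
    return CatalogResult(catalog_id, fits, failed, data)


# ---------------------------------------------------------------------------
# catalog model frames


def build_fl_frame(bio, env) -> pd.DataFrame:
    """Fry-growth frame, one row per brood year B.

    spring_temp is the March-June mean of calendar year B+1 (the cohort's
    lake growing season); fry = ln escapement of brood B; yearlings = ln of
    age-2 smolts migrating in spring B+2, i.e. brood B-1's age-2 smolts.
    """
    b = bio.data.set_index("brood_year")
    spring = pd.Series(np.asarray(env.spring_mean), index=env.years)
    broods = b.index.to_numpy(int)
    with np.errstate(divide="ignore"):
        fry = np.log(b["escapement"].where(b["escapement"] > 0))
        yearlings = pd.Series(
            np.log(b["n_smolt2"].where(b["n_smolt2"] > 0)), index=b.index)
    out = pd.DataFrame({
        "brood_year": broods,
        "fry_len": b["fry_len_mm"].to_numpy(float),
        "spring_temp": spring.reindex(broods + 1).to_numpy(float),
        "fry": fry.to_numpy(float),
        "yearlings": yearlings.reindex(broods - 1).to_numpy(float),
    })
    out["fry_plus_yearlings"] = out["fry"] + out["yearlings"]
    return out


def build_ac_frame(bio, env, productivity) -> pd.DataFrame:
    """Smolt-age-composition frame, one row per brood year B.

    The response is the smolt-count-based proportion migrating at age 1 (not
    the return-based proportion).  spring_temp_mig and year refer to the
    age-1 migration spring, calendar year B+2; condition is the brood's own
    age-1 smolt condition factor.
    """
    b = bio.data.set_index("brood_year")
    prod = productivity.set_index("brood_year")
    spring = pd.Series(np.asarray(env.spring_mean), index=env.years)
    cond1 = condition_factor(b["len_smolt1_mm"], b["wt_smolt1_g"])
    broods = prod.index.to_numpy(int)
    return pd.DataFrame({
        "brood_year": broods,
        "p_smolt1": prod["p_smolt1"].to_numpy(float),
        "fry_len": b["fry_len_mm"].reindex(broods).to_numpy(float),
        "spring_temp_mig": spring.reindex(broods + 2).to_numpy(float),
        "year": (broods + 2).astype(float),
        "condition": cond1.reindex(broods).to_numpy(float),
    })


def build_sas_frame(bio, sas_by_migration) -> pd.DataFrame:
    """Marine-survival frame: one row per migration year x freshwater age.

    Length is the annual mean smolt length of that age (mm); age2 is the
    age-2 indicator; counts are raw fish.
    """
    b = bio.data.set_index("brood_year")
    rows = sas_by_migration.copy()
    lens = []
    for _, r in rows.iterrows():
        brood = int(r["migration_year"]) - int(r["fw_age"]) - 1
        col = "len_smolt1_mm" if r["fw_age"] == 1 else "len_smolt2_mm"
        lens.append(b[col].get(brood, np.nan))
    rows["length"] = lens
    rows["age2"] = (rows["fw_age"] == 2).astype(float)
    return rows


def build_rs_frame(productivity) -> pd.DataFrame:
    """Deviance-partition frame: ln(R/S) with standardized SAS and S/S."""
    sub = productivity[["brood_year", "rps", "sas", "sps"]].dropna()
    sub = sub[sub["rps"] > 0]
    out = pd.DataFrame({"brood_year": sub["brood_year"].to_numpy(int),
                        "ln_rps": np.log(sub["rps"].to_numpy(float))})
    for col, zcol in (("sas", "sas_z"), ("sps", "sps_z")):
        v = sub[col].to_numpy(float)
        out[zcol] = (v - v.mean()) / v.std(ddof=0)
    return out


def build_dc_frame(bio, env, productivity) -> pd.DataFrame:
    """Direct temperature-productivity frame: ln(R/S), escapement (millions)
    and the cohort's growing-season spring temperature."""
    prod = productivity.set_index("brood_year")
    b = bio.data.set_index("brood_year")
    spring = pd.Series(np.asarray(env.spring_mean), index=env.years)
    broods = prod.index.to_numpy(int)
    rps = prod["rps"].where(prod["rps"] > 0)
    return pd.DataFrame({
        "brood_year": broods,
        "ln_rps": np.log(rps.to_numpy(float)),
        "escapement": b["escapement"].reindex(broods).to_numpy(float) / 1e6,
        "spring_temp": spring.reindex(broods + 1).to_numpy(float),
    })


def build_frames(bio, env, productivity, sas_by_migration
                 ) -> dict[str, pd.DataFrame]:
    """All five catalog model frames keyed by catalog id."""
    return {
        "FL": build_fl_frame(bio, env),
        "AC": build_ac_frame(bio, env, productivity),
        "SAS": build_sas_frame(bio, sas_by_migration),
        "RS": build_rs_frame(productivity),
        "DC": build_dc_frame(bio, env, productivity),
    }


# ---------------------------------------------------------------------------
# headline summaries


def rs_partition(frame: pd.DataFrame) -> dict:
    """Deviance partition of ln(R/S) between marine and freshwater survival.

    Fits RS-1/2/3 on standardized predictors and reports the coefficient
    contrast (percent larger response to SAS than to S/S in RS-1) and the
    single-predictor percent deviance of each phase.
    """
    if frame["ln_rps"].notna().sum() < 10:
        raise ValueError("rs_partition: fewer than 10 complete brood years")
    res = run_catalog("RS", frame)
    fits = {f.id: f for f in res.fits}
    b_sas = fits["RS-1"].terms["sas_z"]["estimate"]
    b_sps = fits["RS-1"].terms["sps_z"]["estimate"]
    return {
        "fits": res,
        "coef_sas": b_sas, "coef_sps": b_sps,
        "contrast_pct": 100.0 * (b_sas / b_sps - 1.0),
        "pct_dev_sas": fits["RS-2"].pct_deviance,
        "pct_dev_sps": fits["RS-3"].pct_deviance,
        "pct_dev_both": fits["RS-1"].pct_deviance,
    }


def fit_ricker_env(frame: pd.DataFrame, k: int = 10) -> FitResult:
    """Ricker stock-recruit model with a spring-temperature smooth (DC-1)."""
    spec = DC_CATALOG[0]
    data = frame.dropna(subset=spec.data_columns).reset_index(drop=True)
    return fit_gam_pspline(spec, data, k=k)


def effect_summaries(fit: FitResult, data: pd.DataFrame) -> dict:
    """Odds-scale effect sizes for a logit-link candidate.

    Per-unit odds changes are 100*(exp(beta)-1) for every linear term.  For a
    marine-survival fit the summary adds predicted survival at each smolt
    age's median observed length (random intercept at 0) and the percent
    survival advantage of age-2 smolts at those medians.
    """
    out = {"odds_pct_per_unit": {
        name: 100.0 * (np.exp(t["estimate"]) - 1.0)
        for name, t in fit.terms.items()
        if name not in ("intercept", "phi", "year_var")
        and np.isfinite(t["estimate"])}}
    if fit.spec.family == "binomial-logit" and "length" in fit.terms:
        med = data.groupby("age2")["length"].median()
        if set(med.index) == {0.0, 1.0}:
            b = {n: t["estimate"] for n, t in fit.terms.items()}
            alpha = b["intercept"]

            def prob(length, age2):
                eta = alpha + b.get("length", 0.0) * length \
                    + b.get("age2", 0.0) * age2
                return 1.0 / (1.0 + np.exp(-eta))

            p1 = prob(med[0.0], 0.0)
            p2 = prob(med[1.0], 1.0)
            out["survival_at_median"] = {"age1": p1, "age2": p2}
            out["median_length"] = {"age1": float(med[0.0]),
                                    "age2": float(med[1.0])}
            out["age2_advantage_pct"] = 100.0 * (p2 / p1 - 1.0)
    return out


def load_catalog_config(path) -> dict[str, tuple[ModelSpec, ...]]:
    """Load user-defined candidate catalogs from a YAML model-spec file.

    Layout::

        FL:
          response: fry_len
          family: normal
          models:
            FL-1: [spring_temp, fry, yearlings]
            FL-3gam: ["s(spring_temp)", fry]
    """
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for cid, block in raw.items():
        specs = tuple(
            ModelSpec(mid, block["response"], tuple(terms), block["family"])
            for mid, terms in block["models"].items())
        out[cid] = specs
    return out
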