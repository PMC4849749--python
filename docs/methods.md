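# Methods

## The analysis chain

The package treats a sockeye salmon stock as a chain of annual state
transitions: spawners (escapement) → fry rearing one summer in a nursery
lake → smolts leaving after one or two freshwater winters → adults returning
after two or three ocean winters. Productivity questions ("is warming
hurting returns per spawner?") are answered twice: by direct correlation
(trend tests, a temperature covariate in the stock-recruit model) and by
fitting every intermediate mechanistic link as its own model. The package's
value is that both routes run on the same validated brood table, so a weak
direct correlation can be interpreted against strong intermediate links.

## Brood-table accounting

Age labels use European notation f.o; the incubation winter is uncounted, so
the return lag from brood year is f + o + 1 years and the smolt migration
lag is a + 1 years for freshwater age a. Broods are flagged complete when
all four major age classes (1.2, 1.3, 2.2, 2.3) have return years inside
the observed span; incomplete broods are excluded from derived metrics by
default. Minor age classes enter total returns but carry no age assignment.
Two proportions that are easy to conflate are kept strictly separate:
`p_fw1` (share of the *returns* that reared one winter — filtered by
age-dependent marine survival) and `p_smolt1` (share of the brood's *smolts*
that migrated at age 1 — the response of the age-composition models).

The productivity index is the residual of the linearized Ricker regression
ln(R/S) = a − bS by OLS. Residuals are invariant to uniform rescaling of
returns (the shift is absorbed by a), which the tests verify numerically.

Brood-level SAS uses the brood's total smolts in the denominator regardless
of the migration-year split; broods missing either smolt-age count are
excluded rather than partially summed.

## Trend tests

Both the OLS and the AR(1)-error model are fitted by full maximum
likelihood (not REML) with identical mean structure (intercept + year), so
the likelihood-ratio statistic 2(ℓ_GLS − ℓ_OLS) is referred to χ²(1); the
AR(1) model is preferred below a configurable 0.05 cutoff, while trend
significance is flagged at α = 0.1 on the preferred model's slope. ρ may be
negative, so the tested value is interior to the parameter space and the
boundary caveat of variance-component LRTs does not apply. The AR(1)
likelihood is computed in O(n) by sequential whitening,
(y_i − ρ^{g_i} y_{i−1})/√(1 − ρ^{2g_i}) with g_i the year gap, which is
exact for arbitrary gap patterns; a dense multivariate-normal oracle in the
test suite confirms equality to 1e−8. β and σ² are profiled analytically and
ρ is maximized by bounded scalar search on (−0.99, 0.99).

Proportion-kind series are arcsine-square-root transformed exactly once,
at fit time. No multiple-testing correction is applied by default (a
Benjamini–Hochberg flag can be layered on the output table by the caller).
Slopes are reported in native units per year.

## Candidate catalogs

All members of a catalog are fitted on the complete cases of the catalog's
largest member, so AICs and weights are comparable. AIC conventions per
family: Gaussian fits count the error variance as a parameter; beta
regression counts the precision φ (negative AICs are normal for
well-fitting proportion models); binomial fits use raw fish counts, which
puts their AICs at magnitudes of 10⁷–10⁹.

*Fry growth (FL).* Density covariates are ln(escapement of the producing
brood) and ln(age-2 smolts migrating the following spring); the combined
"fry + yearlings" term of FL-2 is the sum of the two log indices. GAM
variants replace the temperature coefficient with a penalized cubic
regression spline: B-spline basis of dimension 10 (configurable), knots at
covariate quantiles, the curvature penalty ∫f″² (null space = straight
lines), and the penalty weight chosen by GCV. The smooth's effective degrees
of freedom is the trace of the influence matrix over the spline block.
Smooth-term p-values use the rank-r Wald statistic on the fitted smooth
(r = ⌈edf⌉) rather than a naive RSS-difference F test; under a null smooth
the naive test rejected ~33% at α = 0.1 whereas the rank-r test rejects
~12%, matching the calibration of reference GAM software under GCV
selection. GCV's mild undersmoothing on featureless data is inherited —
deliberately, since the selection criterion is part of the method.

*Age composition (AC).* The response is the smolt-count proportion migrating
at age 1, modeled as Beta(μφ, (1−μ)φ) with logit(μ) linear in fry length,
spring temperature of the migration year (calendar year brood+2, which also
defines the "year" covariate), condition factor, and year. Responses at
exactly 0 or 1 are clamped by (y(n−1)+0.5)/n when enabled (the standard
adjustment; the alternative is a domain error). Percent deviance uses
D = 2(ℓ_sat − ℓ) with both the saturated and the intercept-only null
likelihood evaluated at the fitted model's precision — the convention GAM
software uses for estimated-dispersion families, which keeps the share in
[0, 100]. Predictors are standardized internally for optimizer conditioning
and estimates transformed back to native units.

*Marine survival (SAS).* Survivors among smolts per migration year ×
freshwater age, binomial-logit on raw counts, with smolt length entering as
the annual mean per age (two rows per migration year). Random-intercept
variants share one intercept per migration year across both ages,
a_y ~ N(0, σ²), fitted by adaptive Gauss–Hermite quadrature (15 nodes,
integrand re-centered at each group's Newton mode and scaled by the Laplace
curvature — necessary because raw counts near 10⁸ make the integrand a
near-delta). The optimizer is a standardized-design Nelder–Mead with two σ
starts; standard errors come from the exact observed information via the
missing-information identity (complete-data curvature minus posterior score
variance, evaluated on the quadrature nodes). As σ → 0 the marginal
likelihood converges to the GLM likelihood (tested to 1e−4 relative).
Percent deviance for mixed fits is computed against the fixed-intercept-only
GLM null, so variance absorbed by the year intercepts counts as explained —
the contrast that makes the fixed-effects-only and mixed variants
comparable.

*Partition (RS) and direct check (DC).* RS standardizes SAS and S/S to zero
mean and unit variance so their coefficients on ln(R/S) are directly
comparable; deviance partitioning refits with each predictor alone. DC is
the linear Ricker model plus a GCV-selected temperature smooth, with
escapement expressed in millions of fish to keep the coefficient at a
readable magnitude.

## The simulator as study conditions

Defaults encode the system the analysis was designed for: 60 years of
environment; a shared warming trend of 0.020 °C/yr with AR(1) ρ = 0.32 and
marginal anomaly sd 0.9 °C on an Iliamna-like monthly climatology; ice-out
coupled at −5 d/°C; lognormal escapement around 4 million spawners with a
5-year cycle (amplitude 0.8 on the log scale); fry growth flat below 1.5 °C
and +4.5 mm/°C above, −2.61 mm per ln-spawner, residual sd 2.5 mm; a smolt
age-1 logit of +0.106 per mm, +0.146 per °C, +0.021 per year with
brood-level heterogeneity sd 0.4 (many spawning populations contribute to a
brood, so observed proportions are overdispersed relative to binomial — the
reason the analysis uses a beta family); marine survival logit of +0.060 per
mm with an age-2 offset of −0.402 and a shared migration-year effect of sd
1.0; age-2 smolts 23% longer; ocean-age-2 probabilities 0.60/0.70 by
freshwater age; ~1% minor-age returns. Freshwater production uses a
Ricker-type density term (1e−7 per fish, log-sd 0.35) sized so that marine
survival tends to dominate the productivity variance partition, as observed
in this system; with only ~50 broods per realization the estimated
partition still varies noticeably between simulated datasets, as it would
between real systems. Noise conventions: normal on length scales, lognormal on
abundances, binomial on every survival and age split, at the individual-fish
level.

What the simulator does *not* emulate: enumeration and ageing error in
counts (smolt abundances are "observed" exactly, so the SAS models'
explained deviance approaches 100% where field data, with method changes
and measurement error, sit lower); size-dependent ocean-age splits; density
feedback from returns to subsequent escapement (escapement is an exogenous
process); and within-season temperature structure. Passing recovery tests
therefore demonstrates estimator correctness under the assumed mechanism,
not robustness to observation error.

Environment and population use seeds derived deterministically from the
top-level seed; identical seeds reproduce emitted CSVs byte for byte.

## Numerical conventions and degenerate inputs

Missing data are empty CSV cells and NaN in memory; zero is always a datum.
Zero denominators in derived metrics yield missing values, never
infinities. Constant or exactly linear series are flagged degenerate in
trend fitting (slope 0/p 1, or R² 1/p 0) and skip the AR(1) arbitration.
Binomial IRLS uses an absolute deviance tolerance of 1e−6 because raw-count
deviances near 10⁹ make the library default unreachable in double
precision. GCV is optimized by a 25-point log₁₀λ grid on [−6, 12] refined
by bounded search; penalties are trace-normalized so the bounds are
portable across problems. The GLMM reports non-convergence rather than
estimates when its two-start optimizer fails to produce a finite likelihood.

## Problem sizes in the test suite

The default suite simulates the 60-year study conditions once for
shared fixtures; distribution-level checks use 500 replicate null series for
the LRT size, 100 short (20-year) runs for conservation accounting, and 100
full-length replicates for parameter recovery — sizes at which binomial and
Monte-Carlo bounds in the assertions are meaningful without being fragile.
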