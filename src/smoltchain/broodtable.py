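"""Brood-table construction and derived productivity / life-history metrics.

A *brood table* credits every returning adult to the brood year in which it
was spawned.  With age written ``f.o`` (f winters of freshwater rearing, o
winters at sea; the incubation winter is not counted) a fish of age f.o
returning in calendar year Y was spawned in brood year ``Y - f - o - 1``, and
a smolt of freshwater age a migrating in year y belongs to brood ``y - a - 1``.

From the assembled table the module derives the quantities a stock assessment
works with: returns per spawner (R/S) and its density-independent Ricker
residual index, smolts per spawner (S/S), smolt-to-adult survival (SAS) at
brood and migration-year-by-age resolution, age-composition proportions, and
smolt condition factor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from smoltchain.tsio import AnnualSeries, BiologicalTable

logger = logging.getLogger(__name__)

MAJOR_AGES = ["1.2", "1.3", "2.2", "2.3"]
_AGE_RE = re.compile(r"^(\d+)[._](\d+)$")


@dataclass(frozen=True)
class AgeClass:
    """European-notation salmon age: f winters in freshwater, o at sea."""

    freshwater_age: int
    ocean_age: int

    @classmethod
    def parse(cls, label: str) -> "AgeClass":
        m = _AGE_RE.match(str(label).strip())
        if not m:
            raise ValueError(f"unparseable age label {label!r}")
        f, o = int(m.group(1)), int(m.group(2))
        if not (1 <= f <= 2 and 1 <= o <= 3):
            raise ValueError(f"age {label!r} outside supported range")
        return cls(f, o)

    @property
    def label(self) -> str:
        return f"{self.freshwater_age}.{self.ocean_age}"

    @property
    def total_age(self) -> int:
        """Calendar years from spawning to return (incubation winter +
        freshwater winters + ocean winters)."""
        return self.freshwater_age + self.ocean_age + 1


def return_lag(age: AgeClass | str) -> int:
    """Years between brood year and return year for an age class."""
    a = age if isinstance(age, AgeClass) else AgeClass.parse(age)
    return a.total_age


def assign_returns_to_broods(returns: pd.DataFrame,
                             brood_span: tuple[int, int] | None = None
                             ) -> pd.DataFrame:
    """Reassign return-year-indexed counts to brood years.

    ``returns`` has columns ``return_year`` plus one count column per age
    label (``r12`` style or ``1.2`` style).  Counts landing outside
    ``brood_span`` (if given) are dropped with a logged total.
    Returns a brood-year-indexed frame with ``r{f}{o}`` columns.
    """
    age_cols = [c for c in returns.columns if c != "return_year"]
    records: dict[int, dict[str, float]] = {}
    dropped = 0.0
    for col in age_cols:
        if len(col) == 3 and col.startswith("r") and col[1:].isdigit():
            age = AgeClass(int(col[1]), int(col[2]))
        else:
            age = AgeClass.parse(col)
        lag = age.total_age
        for _, row in returns.iterrows():
            if not np.isfinite(row[col]):
                continue
            brood = int(row["return_year"]) - lag
            if brood_span and not (brood_span[0] <= brood <= brood_span[1]):
                dropped += row[col]
                continue
            rec = records.setdefault(brood, {})
            key = f"r{age.freshwater_age}{age.ocean_age}"
            rec[key] = rec.get(key, 0.0) + row[col]
    if dropped:
        logger.info("assign_returns_to_broods: dropped %.0f fish outside "
                    "brood span", dropped)
    out = pd.DataFrame.from_dict(records, orient="index").sort_index()
    out.index.name = "brood_year"
    return out.reset_index()


@dataclass
class BroodTableCollection:
    """Per-brood-year spawners, returns by age, totals and smolt counts.

    ``data`` columns: brood_year, S, r12, r13, r22, r23, r_other, R_total,
    n1, n2, complete.  ``complete`` marks broods whose four major age
    classes' return years all fall inside the observed return span.
    """

    data: pd.DataFrame
    return_span: tuple[int, int]

    def complete(self) -> pd.DataFrame:
        return self.data[self.data["complete"]].reset_index(drop=True)


def _infer_return_span(bio: BiologicalTable) -> tuple[int, int]:
    """Last observed return year inferred from the latest brood with a
    non-missing count in each age class."""
    df = bio.data
    last = []
    first = []
    for col, lag in (("r12", 4), ("r13", 5), ("r22", 5), ("r23", 6)):
        obs = df.loc[df[col].notna(), "brood_year"]
        if len(obs):
            last.append(int(obs.max()) + lag)
            first.append(int(obs.min()) + lag)
    if not last:
        raise ValueError("no return observations in biological table")
    return min(first), max(last)


def build_brood_table(bio: BiologicalTable,
                      return_span: tuple[int, int] | None = None
                      ) -> BroodTableCollection:
    """Assemble the brood table from a brood-year-indexed biological table.

    Returns in the input are already credited to brood years (S1-style
    schema); this constructor totals them, attaches smolt counts by
    freshwater age, and flags completeness: a brood year B is complete when
    the return years B+4 (age 1.2) through B+6 (age 2.3) all lie inside
    ``return_span``.  Minor age classes (``r_other``) enter ``R_total`` but
    carry no age assignment.
    """
    if return_span is None:
        return_span = _infer_return_span(bio)
    df = bio.data
    major = df[["r12", "r13", "r22", "r23"]]
    r_other = df["r_other"].fillna(0.0)
    out = pd.DataFrame({
        "brood_year": df["brood_year"].astype(int),
        "S": df["escapement"],
        "r12": df["r12"], "r13": df["r13"],
        "r22": df["r22"], "r23": df["r23"],
        "r_other": df["r_other"],
        "R_total": major.sum(axis=1, skipna=False) + r_other,
        "n1": df["n_smolt1"], "n2": df["n_smolt2"],
    })
    by = out["brood_year"]
    out["complete"] = ((by + 4 >= return_span[0]) &
                       (by + 6 <= return_span[1]) &
                       major.notna().all(axis=1))
    return BroodTableCollection(out, return_span)


@dataclass
class RickerFit:
    """Linearized Ricker fit ln(R/S) = a - b*S by OLS.

    ``intercept`` is the log recruits-per-spawner at vanishing density;
    ``slope`` is the coefficient on S (so the Ricker b equals ``-slope``).
    Residuals are the density-independent productivity index.
    """

    intercept: float
    slope: float
    residuals: pd.Series        # indexed by brood year
    loglik: float
    nobs: int


def fit_ricker(bt: BroodTableCollection,
               complete_only: bool = True) -> RickerFit:
    """OLS of ln(R/S) on spawner abundance over usable brood years.

    Broods with S <= 0, R <= 0 or missing values are excluded (logged);
    at least three usable broods are required.
    """
    df = bt.complete() if complete_only else bt.data
    usable = (df["S"] > 0) & (df["R_total"] > 0) \
        & df["S"].notna() & df["R_total"].notna()
    dropped = len(df) - int(usable.sum())
    if dropped:
        logger.info("fit_ricker: excluded %d brood years", dropped)
    if usable.sum() < 3:
        raise ValueError("fit_ricker: fewer than 3 usable brood years")
    sub = df[usable]
    y = np.log(sub["R_total"].to_numpy() / sub["S"].to_numpy())
    X = sm.add_constant(sub["S"].to_numpy())
    res = sm.OLS(y, X).fit()
    resid = pd.Series(res.resid, index=sub["brood_year"].to_numpy(int))
    return RickerFit(float(res.params[0]), float(res.params[1]),
                     resid, float(res.llf), int(res.nobs))


def productivity_index(fit: RickerFit) -> AnnualSeries:
    """Ricker residual series: the density-independent R/S index."""
    return AnnualSeries("rps_index", fit.residuals.index.to_numpy(int),
                        fit.residuals.to_numpy(), kind="productivity",
                        axis="brood_year")


def survival_metrics(bt: BroodTableCollection,
                     ricker: RickerFit | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the per-brood productivity table and migration-year survival.

    Returns ``(productivity, sas_by_migration)``:

    productivity columns (one row per complete brood year):
        rps, rps_index, sps, sas, p_fw1, p_oc2, p_smolt1
    sas_by_migration columns (one row per migration year x freshwater age):
        migration_year, fw_age, n_smolts, n_returns, sas

    Zero denominators yield missing values, never infinities.  Brood-level
    S/S and SAS use total smolts of the brood and require both smolt-age
    counts; p_fw1 (share of the *return* that reared one winter) and
    p_smolt1 (share of the brood's *smolts* migrating at age 1) are distinct
    and kept under separate names.
    """
    df = bt.complete().copy()

    def safe_div(num, den):
        den = den.where(den > 0)
        return num / den

    n_tot = df["n1"] + df["n2"]
    fw1 = df["r12"] + df["r13"]
    oc2 = df["r12"] + df["r22"]
    major = df[["r12", "r13", "r22", "r23"]].sum(axis=1, skipna=False)
    prod = pd.DataFrame({
        "brood_year": df["brood_year"],
        "rps": safe_div(df["R_total"], df["S"]),
        "sps": safe_div(n_tot, df["S"]),
        "sas": safe_div(df["R_total"], n_tot),
        "p_fw1": safe_div(fw1, major),
        "p_oc2": safe_div(oc2, major),
        "p_smolt1": safe_div(df["n1"], n_tot),
    })
    if ricker is not None:
        prod["rps_index"] = prod["brood_year"].map(ricker.residuals)
    else:
        prod["rps_index"] = np.nan

    rows = []
    for _, r in df.iterrows():
        by = int(r["brood_year"])
        for age, n_col, ret in ((1, "n1", r["r12"] + r["r13"]),
                                (2, "n2", r["r22"] + r["r23"])):
            n = r[n_col]
            if not np.isfinite(n) or n <= 0 or not np.isfinite(ret):
                continue
            rows.append({"migration_year": by + age + 1, "fw_age": age,
                         "n_smolts": n, "n_returns": ret, "sas": ret / n})
    sas_mig = pd.DataFrame(rows, columns=["migration_year", "fw_age",
                                          "n_smolts", "n_returns", "sas"])
    cols = ["brood_year", "rps", "rps_index", "sps", "sas",
            "p_fw1", "p_oc2", "p_smolt1"]
    return prod[cols], sas_mig.sort_values(
        ["migration_year", "fw_age"]).reset_index(drop=True)


def condition_factor(lengths: pd.Series, weights: pd.Series) -> pd.Series:
    """Condition factor: residuals of ln(weight) on ln(length), pooled.

    Length-weight allometry is fitted by OLS across all years supplied (per
    freshwater age the caller pools its own series); nonpositive or missing
    pairs are excluded with a log entry.  The residual measures weight at a
    given length relative to the population allometry.
    """
    L = pd.Series(lengths, dtype=float)
    W = pd.Series(weights, dtype=float).reindex(L.index)
    ok = (L > 0) & (W > 0) & L.notna() & W.notna()
    if (~ok).sum():
        logger.info("condition_factor: excluded %d nonpositive/missing pairs",
                    int((~ok).sum()))
    if ok.sum() < 3:
        raise ValueError("condition_factor: fewer than 3 usable pairs")
    X = sm.add_constant(np.log(L[ok].to_numpy()))
    res = sm.OLS(np.log(W[ok].to_numpy()), X).fit()
    out = pd.Series(np.nan, index=L.index)
    out[ok] = res.resid
    return out
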