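"""Read, validate and write the annual biological and environmental tables.

Two CSV schemas are supported, mirroring the shape of agency-reported annual
time series for a sockeye salmon system:

``biological.csv`` (one row per brood year)
    brood_year, escapement, r12, r13, r22, r23, r_other,
    smolt_year_age1, n_smolt1, len_smolt1_mm, wt_smolt1_g,
    smolt_year_age2, n_smolt2, len_smolt2_mm, wt_smolt2_g,
    fry_len_mm, smolt_median_doy

``environmental.csv`` (one row per calendar year)
    year, t_jan..t_dec, iceout_doy, h2o_june_c,
    pdo_a, pdo_w, npi, enso, ao, npgo, pna, may_sst, stm2, pisst

Missing measurements are empty cells in CSV and NaN in memory; zeros are data,
never missing.  Derived seasonal covariates (spring and autumn means, growing
season degree days, winter mean low, spawning-season mean high) are computed
from the monthly columns with documented, configurable month windows.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTH_COLS = [f"t_{m}" for m in
              ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]]

MARINE_INDEX_COLS = ["pdo_a", "pdo_w", "npi", "enso", "ao", "npgo",
                     "pna", "may_sst", "stm2", "pisst"]

BIOLOGICAL_COLS = [
    "brood_year", "escapement", "r12", "r13", "r22", "r23", "r_other",
    "smolt_year_age1", "n_smolt1", "len_smolt1_mm", "wt_smolt1_g",
    "smolt_year_age2", "n_smolt2", "len_smolt2_mm", "wt_smolt2_g",
    "fry_len_mm", "smolt_median_doy",
]

ENVIRONMENTAL_COLS = (["year"] + MONTH_COLS +
                      ["iceout_doy", "h2o_june_c"] + MARINE_INDEX_COLS)


class SchemaError(ValueError):
    """A mandatory column is missing or a cell fails to parse."""


@dataclass(frozen=True)
class SeasonWindows:
    """Month windows defining the derived seasonal covariates.

    The analysis treats these as conventions, not data: spring is the
    March-June lake pre-season, autumn September-November.  Winter mean low
    spans December of the *prior* calendar year through February; the
    spawning season is July-September.  Growing-season degree days accumulate
    positive monthly means over May-September, weighted by days in month.
    """

    spring: tuple[int, ...] = (3, 4, 5, 6)
    autumn: tuple[int, ...] = (9, 10, 11)
    winter: tuple[int, ...] = (-12, 1, 2)   # negative = prior calendar year
    spawning: tuple[int, ...] = (7, 8, 9)
    degree_day_months: tuple[int, ...] = (5, 6, 7, 8, 9)


@dataclass(frozen=True)
class AnnualSeries:
    """A single named annual time series with a variable-kind tag.

    ``kind`` steers downstream handling: series tagged ``proportion`` are
    arcsine-square-root transformed before trend fitting, and proportions must
    lie in [0, 1].
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    kind: str = "index"
    axis: str = "year"    # "year" (calendar) or "brood_year"

    _KINDS = ("abundance", "productivity", "proportion", "growth",
              "phenology", "temperature", "index")

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.shape != values.shape:
            raise ValueError("years and values must have equal length")
        if len(years) and np.any(np.diff(years) <= 0):
            raise ValueError(f"{self.name}: years must be strictly increasing")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        obs = values[np.isfinite(values)]
        if self.kind == "proportion" and len(obs) and (
                obs.min() < -1e-12 or obs.max() > 1 + 1e-12):
            raise ValueError(f"{self.name}: proportions outside [0, 1]")
        if self.kind == "abundance" and len(obs) and obs.min() < 0:
            raise ValueError(f"{self.name}: negative abundance")

    def dropna(self) -> "AnnualSeries":
        keep = np.isfinite(self.values)
        return AnnualSeries(self.name, self.years[keep], self.values[keep],
                            self.kind, self.axis)

    def __len__(self) -> int:
        return len(self.years)


def _validate(df: pd.DataFrame, required: list[str], label: str) -> pd.DataFrame:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{label}: missing mandatory column {col!r}")
    out = df.copy()
    for col in required:
        try:
            out[col] = pd.to_numeric(out[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise SchemaError(
                f"{label}: non-numeric cell in column {col!r}, row {row}"
            ) from exc
    return out


@dataclass
class BiologicalTable:
    """Brood-year-indexed biological table (S1-style schema).

    Returns by age class are already credited to the brood year that produced
    them; smolt counts carry their migration year alongside so that
    migration-year-indexed survival metrics can be reconstructed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = _validate(self.data, BIOLOGICAL_COLS, "biological table")
        df = df.sort_values("brood_year").reset_index(drop=True)
        if df["brood_year"].duplicated().any():
            raise SchemaError("biological table: duplicate brood years")
        counts = ["escapement", "r12", "r13", "r22", "r23", "r_other",
                  "n_smolt1", "n_smolt2"]
        neg = [c for c in counts if (df[c].dropna() < 0).any()]
        if neg:
            raise SchemaError(f"biological table: negative counts in {neg}")
        self.data = df

    @property
    def brood_years(self) -> np.ndarray:
        return self.data["brood_year"].to_numpy(dtype=int)

    def series(self, column: str, kind: str = "index") -> AnnualSeries:
        sub = self.data[["brood_year", column]].dropna()
        return AnnualSeries(column, sub["brood_year"].to_numpy(dtype=int),
                            sub[column].to_numpy(dtype=float), kind,
                            axis="brood_year")


@dataclass
class EnvironmentalTable:
    """Calendar-year environmental table with derived seasonal covariates."""

    data: pd.DataFrame
    windows: SeasonWindows = field(default_factory=SeasonWindows)
    imputed_iceout: np.ndarray | None = None

    def __post_init__(self) -> None:
        df = _validate(self.data, ENVIRONMENTAL_COLS, "environmental table")
        df = df.sort_values("year").reset_index(drop=True)
        if df["year"].duplicated().any():
            raise SchemaError("environmental table: duplicate years")
        tmon = df[MONTH_COLS].to_numpy(dtype=float)
        obs = tmon[np.isfinite(tmon)]
        if len(obs) and (obs.min() < -40 or obs.max() > 30):
            raise SchemaError("environmental table: monthly temperature "
                              "outside [-40, 30] degC")
        ice = df["iceout_doy"].dropna()
        if len(ice) and ((ice < 60) | (ice > 200)).any():
            raise SchemaError("environmental table: ice-out day-of-year "
                              "outside [60, 200]")
        self.data = df
        if self.imputed_iceout is None:
            self.imputed_iceout = np.zeros(len(df), dtype=bool)

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy(dtype=int)

    def _season_mean(self, months: tuple[int, ...]) -> pd.Series:
        """Mean of monthly means; negative month numbers read from the
        previous calendar year's row (e.g. -12 = prior December)."""
        parts = []
        for m in months:
            col = self.data[MONTH_COLS[abs(m) - 1]]
            parts.append(col.shift(1) if m < 0 else col)
        return pd.concat(parts, axis=1).mean(axis=1, skipna=False)

    @property
    def spring_mean(self) -> pd.Series:
        return self._season_mean(self.windows.spring)

    @property
    def autumn_mean(self) -> pd.Series:
        return self._season_mean(self.windows.autumn)

    @property
    def winter_mean_low(self) -> pd.Series:
        return self._season_mean(self.windows.winter)

    @property
    def spawning_mean_high(self) -> pd.Series:
        return self._season_mean(self.windows.spawning)

    @property
    def degree_days(self) -> pd.Series:
        """Growing-season degree days: sum of max(0, monthly mean) times
        days-in-month over the configured window (degC-day, non-leap)."""
        total = pd.Series(0.0, index=self.data.index)
        for m in self.windows.degree_day_months:
            ndays = calendar.monthrange(2001, m)[1]
            total = total + self.data[MONTH_COLS[m - 1]].clip(lower=0) * ndays
        return total

    def series(self, column: str, kind: str = "temperature") -> AnnualSeries:
        derived = {"spring_mean": self.spring_mean,
                   "autumn_mean": self.autumn_mean,
                   "winter_mean_low": self.winter_mean_low,
                   "spawning_mean_high": self.spawning_mean_high,
                   "degree_days": self.degree_days}
        vals = derived[column] if column in derived else self.data[column]
        keep = vals.notna().to_numpy()
        return AnnualSeries(column, self.years[keep],
                            vals.to_numpy(dtype=float)[keep], kind)


def read_biological(path) -> BiologicalTable:
    """Read and validate a biological CSV; empty cells become NaN."""
    return BiologicalTable(pd.read_csv(path))


def read_environmental(path, windows: SeasonWindows | None = None
                       ) -> EnvironmentalTable:
    """Read and validate an environmental CSV; empty cells become NaN."""
    df = pd.read_csv(path)
    return EnvironmentalTable(df, windows or SeasonWindows())


def write_biological(table: BiologicalTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_environmental(table: EnvironmentalTable, path) -> None:
    table.data.to_csv(path, index=False)


def impute_iceout(env: EnvironmentalTable, max_missing_frac: float = 0.05
                  ) -> EnvironmentalTable:
    """Fill missing ice-out dates by a two-predictor linear regression.

    Missing ice-out days-of-year are predicted from winter mean low and
    spawning-season (spring proxy) mean high temperature, fitted by OLS on the
    complete years.  Observed values are never altered; imputed rows are
    flagged in ``imputed_iceout``.

    Raises if fewer than 10 complete years are available; logs a warning when
    the missing fraction exceeds ``max_missing_frac``.
    """
    df = env.data.copy()
    ice = df["iceout_doy"]
    winter = env.winter_mean_low
    # Monthly means stand in for daily highs: spring-season mean is the
    # "spring mean high" proxy available at monthly resolution.
    spring_pred = env.spring_mean
    miss = ice.isna() & winter.notna() & spring_pred.notna()
    if not miss.any():
        return env
    frac = ice.isna().mean()
    if frac > max_missing_frac:
        logger.warning("ice-out missing fraction %.1f%% exceeds %.0f%%",
                       100 * frac, 100 * max_missing_frac)
    train = ice.notna() & winter.notna() & spring_pred.notna()
    if train.sum() < 10:
        raise ValueError("impute_iceout: fewer than 10 complete years")
    X = np.column_stack([np.ones(train.sum()), winter[train], spring_pred[train]])
    beta, *_ = np.linalg.lstsq(X, ice[train].to_numpy(), rcond=None)
    Xm = np.column_stack([np.ones(miss.sum()), winter[miss], spring_pred[miss]])
    pred = Xm @ beta
    df.loc[miss, "iceout_doy"] = np.clip(pred, 60, 200)
    flags = env.imputed_iceout.copy()
    flags[miss.to_numpy()] = True
    return EnvironmentalTable(df, env.windows, flags)


def arcsin_sqrt(p):
    """Arcsine-square-root (angular) transform of a proportion, in radians.

    Vectorized; raises on values outside [0, 1] beyond a 1e-12 tolerance.
    """
    arr = np.asarray(p, dtype=float)
    obs = arr[np.isfinite(arr)]
    if len(obs) and (obs.min() < -1e-12 or obs.max() > 1 + 1e-12):
        raise ValueError("arcsin_sqrt: input outside [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return float(out) if np.isscalar(p) else out
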