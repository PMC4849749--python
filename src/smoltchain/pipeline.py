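"""End-to-end orchestration: tables -> brood table -> trends -> catalogs.

The pipeline is a plain function over the library so it can be driven by the
CLI, by tests, or interactively.  Every stage writes its CSV into the run
directory and the run closes with a manifest (input digests, config, seed,
row counts, outputs) that is identical across reruns of the same
inputs+config+seed apart from timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from smoltchain import broodtable as bt
from smoltchain import mechmodels as mm
from smoltchain import trends as tr
from smoltchain.tsio import BiologicalTable, EnvironmentalTable, impute_iceout

DEFAULT_CONFIG = {
    "trend_alpha": 0.1,
    "lrt_alpha": 0.05,
    "beta_clamp": True,
    "gam_basis_dim": 10,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(bio: BiologicalTable, env: EnvironmentalTable,
                 out_dir, config: dict | None = None,
                 seed: int | None = None,
                 input_paths: dict | None = None) -> dict:
    """Run brood-table accounting, trend tests and all five model catalogs.

    Returns the manifest dict (also written as ``manifest.json``).  Outputs:
    brood_table.csv, productivity.csv, sas_by_migration.csv, trends.csv,
    fl.csv/ac.csv/sas.csv/rs.csv/dc.csv, effects.csv.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "seed": seed, "stages": {},
                      "outputs": []}
    if input_paths:
        manifest["inputs"] = {k: _digest(Path(p))
                              for k, p in input_paths.items()}

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0,
                                                     3)}
        return result

    def write(name, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)
        return path

    env = stage("impute_iceout", lambda: impute_iceout(env))

    def brood_stage():
        coll = bt.build_brood_table(bio)
        fit = bt.fit_ricker(coll)
        prod, sas_mig = bt.survival_metrics(coll, fit)
        return coll, fit, prod, sas_mig

    coll, ricker, prod, sas_mig = stage("broodtable", brood_stage)
    write("brood_table.csv", coll.data)
    write("productivity.csv", prod)
    write("sas_by_migration.csv", sas_mig)
    manifest["stages"]["broodtable"]["rows"] = len(coll.data)
    manifest["ricker"] = {"intercept": ricker.intercept,
                          "slope": ricker.slope, "n": ricker.nobs}

    def trend_stage():
        catalog = tr.default_catalog(bio, env, prod)
        return tr.trend_table(catalog, alpha=cfg["trend_alpha"],
                              lrt_alpha=cfg["lrt_alpha"])
    trend_df = stage("trends", trend_stage)
    write("trends.csv", trend_df)
    manifest["stages"]["trends"]["rows"] = len(trend_df)

    frames = stage("frames", lambda: mm.build_frames(bio, env, prod, sas_mig))
    catalogs: dict[str, mm.CatalogResult] = {}
    for cid in ("FL", "AC", "SAS", "RS", "DC"):
        kw = {}
        if cid == "FL":
            kw["k"] = cfg["gam_basis_dim"]
        if cid == "AC":
            kw["clamp"] = cfg["beta_clamp"]
        res = stage(f"catalog_{cid}", lambda c=cid, k=kw:
                    mm.run_catalog(c, frames[c], **k))
        catalogs[cid] = res
        write(f"{cid.lower()}.csv", res.report())
        manifest["stages"][f"catalog_{cid}"]["models"] = len(res.fits)
        manifest["stages"][f"catalog_{cid}"]["failed"] = sorted(res.failed)

    def effects_stage():
        rows = []
        for cid in ("AC", "SAS"):
            res = catalogs[cid]
            if not res.fits:
                continue
            best = res.best()
            summ = mm.effect_summaries(best, res.data)
            for term, pct in summ["odds_pct_per_unit"].items():
                rows.append({"catalog": cid, "model_id": best.id,
                             "quantity": f"odds_pct_per_{term}",
                             "value": pct})
            if "age2_advantage_pct" in summ:
                rows.append({"catalog": cid, "model_id": best.id,
                             "quantity": "age2_survival_advantage_pct",
                             "value": summ["age2_advantage_pct"]})
        try:
            part = mm.rs_partition(frames["RS"])
            for key in ("contrast_pct", "pct_dev_sas", "pct_dev_sps"):
                rows.append({"catalog": "RS", "model_id": "RS-1/2/3",
                             "quantity": key, "value": part[key]})
        except ValueError:
            pass
        return pd.DataFrame(rows)

    effects = stage("effects", effects_stage)
    write("effects.csv", effects)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def render_report(run_dir) -> str:
    """Render the run directory's CSVs as aligned text tables.

    Trend rows significant at the configured level are marked '*'; catalog
    tables echo AIC, weight and percent deviance.  Every number is read back
    from a CSV cell; nothing is recomputed here.
    """
    run = Path(run_dir)
    chunks = []
    trends_path = run / "trends.csv"
    if trends_path.exists():
        df = pd.read_csv(trends_path)
        ok = df[df["status"] == "ok"].copy()
        ok["sig"] = np.where(ok["significant"], "*", "")
        cols = ["variable", "ols_slope", "r2", "ols_p", "gls_slope",
                "rho", "lrt_p", "preferred", "sig"]
        chunks.append("== Trend analysis ==\n"
                      + ok[cols].to_string(index=False,
                                           float_format=lambda v: f"{v:.3f}"))
        skipped = df[df["status"] != "ok"]
        if len(skipped):
            chunks.append("skipped: "
                          + ", ".join(skipped["variable"].astype(str)))
    else:
        chunks.append("[warning] trends.csv missing; partial report")
    for cid in ("fl", "ac", "sas", "rs", "dc"):
        path = run / f"{cid}.csv"
        if not path.exists():
            chunks.append(f"[warning] {cid}.csv missing")
            continue
        df = pd.read_csv(path)
        chunks.append(f"== Catalog {cid.upper()} ==\n"
                      + df.to_string(index=False,
                                     float_format=lambda v: f"{v:.4g}"))
        if "aic_weight" in df and df["aic_weight"].notna().any():
            wsum = df.drop_duplicates("model_id")["aic_weight"].sum()
            chunks.append(f"(AIC weights sum to {wsum:.2f})")
    eff = run / "effects.csv"
    if eff.exists():
        df = pd.read_csv(eff)
        if len(df):
            chunks.append("== Effect summaries ==\n"
                          + df.to_string(index=False,
                                         float_format=lambda v: f"{v:.3f}"))
    return "\n\n".join(chunks) + "\n"
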