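"""End-to-end pipeline orchestration from a single run configuration.

Stages run in method order — simulate (optional) -> predictability metrics
-> record prep / QC -> model fitting -> grid prediction -> literature
validation — each writing delimited-text outputs into the run directory,
with a JSON manifest (config hash, seeds, per-stage outputs, warnings)
sufficient to rerun the identical analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colwell import site_predictability_table
from . import records as rp
from . import simulate as sim
from . import spatial as sp
from . import validation as val
from .model import ModelSpec, compare, fit as fit_model

log = logging.getLogger("phenosync")

DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "phenosync_run",
    "simulate": {"enabled": False, "preset": "small"},
    "colwell": {"enabled": True, "series": None, "n_states": 11,
                "strategy": "equal_width", "window_days": 45, "polyorder": 2},
    "prep": {"enabled": True, "records": None, "qc": True,
             "taus": [0.1, 0.5, 0.9], "alpha": 0.05, "n_boot": 200},
    "fit": {"enabled": True, "models": ["null", "latitude_elevation",
                                        "colwell_elevation", "colwell_only"]},
    "predict_grid": {"enabled": False, "grid": None, "model": "colwell_elevation"},
    "validate": {"enabled": False, "literature": None, "min_n": 30,
                 "model": "colwell_elevation"},
}


def load_config(path) -> dict:
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run(config: dict, output_dir=None) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "config_hash": _config_hash(cfg), "seed": seed,
                "stages": {}, "warnings": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _run_stages(cfg, out, seed, manifest)
        except Exception as err:
            manifest["failed_stage"] = manifest.get("current_stage", "?")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(
                f"stage {manifest['failed_stage']!r} failed: {err}") from err
        manifest["warnings"] = [str(w.message) for w in caught]
    manifest.pop("current_stage", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stages(cfg, out, seed, manifest):
    series = records = grid = None

    if cfg["simulate"]["enabled"]:
        manifest["current_stage"] = "simulate"
        preset = cfg["simulate"].get("preset", "small")
        scen = (sim.paper_like_scenario() if preset == "paper_like"
                else sim.small_scenario())
        records, truth = sim.gen_population(scen, seed)
        env_scen = sim.EnvScenario(sites=tuple(truth["region_table"]["region_id"]))
        series = sim.gen_environment(env_scen, seed + 1)
        grid = sim.gen_grid_covariates(200, seed + 2)
        records.to_csv(out / "records.csv", index=False)
        series.to_csv(out / "series.csv", index=False)
        grid.to_csv(out / "grid_covariates.csv", index=False)
        manifest["stages"]["simulate"] = {
            "outputs": ["records.csv", "series.csv", "grid_covariates.csv"],
            "preset": preset}
    else:
        manifest["stages"]["simulate"] = "skipped"

    if cfg["colwell"]["enabled"]:
        manifest["current_stage"] = "colwell"
        if series is None:
            series = pd.read_csv(cfg["colwell"]["series"], parse_dates=["date"])
        c = cfg["colwell"]
        metrics = site_predictability_table(
            series, n_states=c["n_states"], strategy=c["strategy"],
            window_days=c["window_days"], polyorder=c["polyorder"])
        metrics.to_csv(out / "colwell_metrics.csv", index=False)
        meta = {"n_states": c["n_states"], "strategy": c["strategy"],
                "window_days": c["window_days"], "polyorder": c["polyorder"]}
        (out / "colwell_metadata.json").write_text(json.dumps(meta, indent=2))
        manifest["stages"]["colwell"] = {
            "outputs": ["colwell_metrics.csv", "colwell_metadata.json"]}
    else:
        manifest["stages"]["colwell"] = "skipped"

    table = consts = None
    if cfg["prep"]["enabled"]:
        manifest["current_stage"] = "prep"
        if records is None:
            records = pd.read_csv(cfg["prep"]["records"])
        censored = rp.censor_records(records)
        p = cfg["prep"]
        if p["qc"]:
            qc = rp.quantile_trend_screen(censored, taus=tuple(p["taus"]),
                                          alpha=p["alpha"], n_boot=p["n_boot"],
                                          seed=seed + 3)
            qc.to_csv(out / "qc_report.csv", index=False)
            bad = qc.loc[qc["excluded"], "region_id"].unique()
            for r in bad:
                log.warning("region %s excluded by quantile trend screen", r)
            censored = censored[~censored["region_id"].isin(bad)]
            qc_out = ["qc_report.csv"]
        else:
            qc_out = []
        cov_cols = [c for c in censored.columns
                    if c.startswith(("constancy_", "contingency_"))
                    or c in ("elevation", "latitude")]
        table, consts = rp.attach_covariates(
            censored, censored[["region_id"]].drop_duplicates(),
            covariate_columns=cov_cols)
        table.to_csv(out / "model_table.csv", index=False)
        consts.to_csv(out / "standardization.csv", index=False)
        manifest["stages"]["prep"] = {
            "outputs": ["model_table.csv", "standardization.csv"] + qc_out,
            "qc": bool(p["qc"])}
    else:
        manifest["stages"]["prep"] = "skipped"

    fits = {}
    if cfg["fit"]["enabled"] and table is not None:
        manifest["current_stage"] = "fit"
        summaries = []
        for name in cfg["fit"]["models"]:
            spec = ModelSpec.preset(name)
            f = fit_model(spec, table, standardization=consts, seed=seed + 4)
            fits[name] = f
            coefs = pd.concat([
                f.beta.rename(lambda c: f"beta.{c}"),
                f.gamma.rename(lambda c: f"gamma.{c}"),
                pd.Series({"tau": f.tau, "loglik": f.loglik, "AIC": f.aic,
                           "converged": float(f.converged)}),
            ])
            coefs.rename_axis("parameter").rename(name).to_csv(
                out / f"fit_{name}.csv", header=True)
            summaries.append(f)
        cmp_tbl = compare(summaries, reference=summaries[0])
        cmp_tbl.to_csv(out / "model_comparison.csv", index=False)
        manifest["stages"]["fit"] = {
            "outputs": [f"fit_{n}.csv" for n in fits] + ["model_comparison.csv"]}
    else:
        manifest["stages"]["fit"] = "skipped"

    if cfg["predict_grid"]["enabled"] and fits:
        manifest["current_stage"] = "predict_grid"
        if grid is None:
            grid = pd.read_csv(cfg["predict_grid"]["grid"])
        f = fits[cfg["predict_grid"].get("model", "colwell_elevation")]
        surf = sp.predict_surface(f, grid)
        surf.points.to_csv(out / "surface.csv", index=False)
        surf.summary.to_csv(out / "surface_summary.csv", index=False)
        (out / "surface.geojson").write_text(sp.surface_to_geojson(surf))
        manifest["stages"]["predict_grid"] = {
            "outputs": ["surface.csv", "surface_summary.csv", "surface.geojson"]}
    else:
        manifest["stages"]["predict_grid"] = "skipped"

    if cfg["validate"]["enabled"]:
        manifest["current_stage"] = "validate"
        v = cfg["validate"]
        lit = (pd.read_csv(v["literature"]) if v.get("literature")
               else val.load_literature_table())
        if fits and v.get("model") in fits:
            lit = val.predict_for_sites(fits[v["model"]], lit)
            rep = val.validate(lit, min_n=v["min_n"])
        else:
            rep = val.validate(lit, pred_mean_col="pred_mean_latelev",
                               pred_synch_col="pred_synch_latelev",
                               min_n=v["min_n"])
        val.diff_table(rep).to_csv(out / "validation.csv", index=False)
        (out / "validation_summary.json").write_text(json.dumps(
            {"mae_mean": rep.mae_mean, "mae_synchrony": rep.mae_synchrony,
             "n_excluded": len(rep.excluded)}, indent=2))
        manifest["stages"]["validate"] = {
            "outputs": ["validation.csv", "validation_summary.json"]}
    else:
        manifest["stages"]["validate"] = "skipped"
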