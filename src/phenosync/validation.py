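"""Out-of-sample validation against published parturition distributions.

Model predictions are compared to independently reported regional means and
synchronies (an 80% interval width) compiled from the European literature.
Sites with small samples (n <= ``min_n``) are excluded; sites missing one
of the two reported quantities contribute only to the metric they report.
The headline score is the mean absolute error (MAE) over included sites,
separately for the mean date and for synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .model import FittedICLS, predict


def load_literature_table() -> pd.DataFrame:
    """The packaged literature table of reported parturition distributions.

    Columns: site, period, n, reported mean day-of-year, reported synchrony
    (80% interval, days) and the two models' published predictions for both
    quantities (used when validating against precomputed predictions).
    """
    with resources.files("phenosync.data").joinpath("literature_table1.csv").open() as f:
        return pd.read_csv(f)


@dataclass
class ValidationReport:
    per_site: pd.DataFrame
    excluded: pd.DataFrame
    mae_mean: float
    mae_synchrony: float


def validate(
    literature: pd.DataFrame,
    pred_mean_col: str = "pred_mean",
    pred_synch_col: str = "pred_synch",
    min_n: int = 30,
) -> ValidationReport:
    """Score predictions against the literature table.

    ``literature`` must carry ``reported_mean_doy`` / ``reported_synchrony80``
    and the two prediction columns (add them with
    :func:`predict_for_sites` when validating a fit).  Sites with a known
    n <= ``min_n`` are excluded (sites with unknown n are retained and
    logged); differences are predicted - reported.
    """
    lit = literature.copy()
    known_n = pd.to_numeric(lit.get("n"), errors="coerce")
    excl_mask = known_n.notna() & (known_n <= min_n)
    excluded = lit[excl_mask].copy()
    excluded["reason"] = f"n <= {min_n}"
    kept = lit[~excl_mask].copy()
    if kept.empty:
        raise ValueError("no sites remain after exclusions")

    kept["diff_mean"] = kept[pred_mean_col] - kept["reported_mean_doy"]
    kept["diff_synch"] = kept[pred_synch_col] - kept["reported_synchrony80"]
    mae_mean = float(kept["diff_mean"].abs().mean())
    mae_synch = float(kept["diff_synch"].abs().mean())
    return ValidationReport(per_site=kept, excluded=excluded,
                            mae_mean=mae_mean, mae_synchrony=mae_synch)


def predict_for_sites(fit: FittedICLS, sites: pd.DataFrame,
                      standardization: pd.DataFrame | None = None,
                      pred_mean_col: str = "pred_mean",
                      pred_synch_col: str = "pred_synch") -> pd.DataFrame:
    """Attach a fit's conditional predictions to a site covariate table."""
    consts = standardization if standardization is not None else fit.standardization
    work = sites.copy()
    if consts is not None:
        for _, row in consts.iterrows():
            if row["covariate"] in work.columns:
                work[row["covariate"]] = ((work[row["covariate"]] - row["mean"])
                                          / row["sd"])
    out = sites.copy()
    mus, syn = [], []
    for r in work.to_dict("records"):
        p = predict(fit, r)
        mus.append(p.mu)
        syn.append(p.synchrony80)
    out[pred_mean_col] = mus
    out[pred_synch_col] = syn
    return out


def diff_table(report: ValidationReport) -> pd.DataFrame:
    """Flat site-by-site table in the literature-comparison layout."""
    if report.per_site.empty:
        raise ValueError("empty validation report")
    cols = ["site", "reported_mean_doy", "diff_mean",
            "reported_synchrony80", "diff_synch"]
    out = report.per_site.copy()
    pred_cols = [c for c in out.columns if c.startswith("pred_")]
    return out[["site"] + pred_cols + cols[1:]] if "site" in out.columns else out
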