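"""Birth-record preparation: interval censoring and sampling-bias screening.

Back-calculated parturition dates (marking day minus estimated fawn age)
carry age-dependent uncertainty, so each record becomes an interval
[birth - delta, birth + delta] on the day-of-year axis with a half-width that
widens with estimated age.  Regions whose fawn searches drifted earlier
over the years (an artefact of mowing-driven search effort, not of deer
phenology) are flagged by a quantile-regression trend screen and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

#: (max age in days, interval half-width in days); ages above the last
#: boundary take the final half-width
DEFAULT_CENSOR_RULE = ((7, 2.0), (14, 3.0), (np.inf, 5.0))

AGE_CLASS_NAMES = ("young", "mid", "old")


@dataclass
class CensoredObservation:
    lower_doy: float
    upper_doy: float
    age_class: str
    record_id: object


def censor_halfwidth(age_days, rule=DEFAULT_CENSOR_RULE):
    """Half-width of the censoring interval for an estimated fawn age.

    Default rule: age <= 7 d -> +-2; 8-14 d -> +-3; >= 15 d -> +-5.
    Vectorised over ``age_days``.
    """
    age = np.asarray(age_days, dtype=float)
    if (age < 0).any():
        raise ValueError("estimated fawn age must be non-negative")
    delta = np.full(age.shape, rule[-1][1])
    for bound, hw in reversed(rule[:-1]):
        delta = np.where(age <= bound, hw, delta)
    return delta


def censor_age_class(age_days, rule=DEFAULT_CENSOR_RULE):
    age = np.asarray(age_days, dtype=float)
    cls = np.full(age.shape, AGE_CLASS_NAMES[-1], dtype=object)
    for name, (bound, _) in zip(reversed(AGE_CLASS_NAMES[:-1]), reversed(rule[:-1])):
        cls = np.where(age <= bound, name, cls)
    return cls


def censor_interval(record, rule=DEFAULT_CENSOR_RULE) -> CensoredObservation:
    """Build the censoring interval for one birth record.

    ``record`` is any mapping with ``estimated_birth_doy`` and
    ``estimated_age_days`` (and optionally ``record_id``).
    """
    age = record["estimated_age_days"]
    if age < 0:
        raise ValueError("estimated fawn age must be non-negative")
    delta = float(censor_halfwidth(age, rule))
    mid = float(record["estimated_birth_doy"])
    return CensoredObservation(
        lower_doy=mid - delta,
        upper_doy=mid + delta,
        age_class=str(censor_age_class(age, rule)),
        record_id=record.get("record_id") if hasattr(record, "get") else record["record_id"],
    )


def censor_records(records: pd.DataFrame, rule=DEFAULT_CENSOR_RULE) -> pd.DataFrame:
    """Vectorised censoring for a records table; adds lower/upper/age_class."""
    out = records.copy()
    delta = censor_halfwidth(out["estimated_age_days"].to_numpy(), rule)
    mid = out["estimated_birth_doy"].to_numpy(float)
    out["lower_doy"] = mid - delta
    out["upper_doy"] = mid + delta
    out["age_class"] = censor_age_class(out["estimated_age_days"].to_numpy(), rule)
    return out


def _quantreg_slope(year: np.ndarray, doy: np.ndarray, tau: float) -> float:
    if np.ptp(doy) == 0:  # constant response: flat fit, QuantReg is degenerate
        return 0.0
    X = sm.add_constant(year.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(doy.astype(float), X).fit(q=tau, max_iter=200)
    return float(res.params[1])


def _quantreg_slopes_batch(X: np.ndarray, Y: np.ndarray, tau: float,
                           n_iter: int = 60, delta: float = 1e-6) -> np.ndarray:
    """Pinball-loss linear fits for many (x, y) datasets at once.

    IRLS on the smoothed check loss, vectorised over the first axis; used
    for the bootstrap replicates, where one statsmodels fit per resample
    would dominate the runtime.  Returns the slope per dataset.
    """
    B, n = X.shape
    a = np.quantile(Y, tau, axis=1)
    b = np.zeros(B)
    for _ in range(n_iter):
        r = Y - a[:, None] - b[:, None] * X
        w = np.where(r > 0, tau, 1.0 - tau) / np.maximum(np.abs(r), delta)
        Sw = w.sum(axis=1)
        Swx = (w * X).sum(axis=1)
        Swxx = (w * X * X).sum(axis=1)
        Swy = (w * Y).sum(axis=1)
        Swxy = (w * X * Y).sum(axis=1)
        det = Sw * Swxx - Swx**2
        bad = np.abs(det) < 1e-12
        det = np.where(bad, 1.0, det)
        a_new = (Swxx * Swy - Swx * Swxy) / det
        b_new = (Sw * Swxy - Swx * Swy) / det
        a = np.where(bad, a, a_new)
        b = np.where(bad, b, b_new)
    return b


def quantile_trend_screen(
    records: pd.DataFrame,
    taus=(0.1, 0.5, 0.9),
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen each region for a drift towards earlier fawn searches.

    For each region and each quantile level tau, fits a linear quantile
    regression (pinball loss) of marking day-of-year on year and derives a
    two-sided p-value for the slope from a seeded case-resampling bootstrap
    of (year, doy) pairs.  A region is flagged ``excluded`` when any tau
    shows a significantly *negative* slope (earlier searches over time) at
    level ``alpha``; positive trends never trigger exclusion.  Because three
    quantile levels are tested per region, the exclusion decision uses
    Bonferroni-adjusted p-values so the familywise false-exclusion rate is
    held at ``alpha`` (both raw and adjusted p-values are reported).

    Returns a tidy report with one row per (region, tau) plus the exclusion
    flag; regions with a single observed year are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region, grp in records.groupby("region_id"):
        year = grp["year"].to_numpy(float)
        doy = grp["marking_doy"].to_numpy(float)
        if len(np.unique(year)) < 2:
            warnings.warn(f"region {region}: single year, trend screen skipped")
            continue
        n = len(grp)
        region_excluded = False
        region_rows = []
        idx = rng.integers(0, n, (n_boot, n))
        Xb, Yb = year[idx], doy[idx]
        valid = np.ptp(Xb, axis=1) > 0
        for tau in taus:
            slope = _quantreg_slope(year, doy, tau)
            if valid.any() and np.ptp(doy) > 0:
                boot = _quantreg_slopes_batch(Xb[valid], Yb[valid], tau)
            else:
                boot = np.array([])
            if boot.size == 0:
                pval = 1.0
            else:
                # percentile bootstrap, two-sided
                p_lo = np.mean(boot <= 0)
                p_hi = np.mean(boot >= 0)
                pval = min(1.0, 2 * min(p_lo, p_hi))
            p_adj = min(1.0, pval * len(taus))
            region_rows.append(
                {"region_id": region, "tau": tau, "slope": slope, "p_value": pval,
                 "p_adjusted": p_adj, "n": n, "alpha": alpha}
            )
            if slope < 0 and p_adj < alpha:
                region_excluded = True
        for r in region_rows:
            r["excluded"] = region_excluded
        rows.extend(region_rows)
    return pd.DataFrame(rows)


def attach_covariates(
    records: pd.DataFrame,
    site_covariates: pd.DataFrame,
    covariate_columns=None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join model covariates onto censored observations and z-score them.

    ``site_covariates`` carries one row per region/site with the covariate
    columns (elevation and latitude, if present, are taken from the records
    themselves).  Returns ``(model_table, constants)`` where ``constants``
    stores the mean and SD used for each standardized column, so raw values
    can be recovered as ``raw = z * sd + mean``.
    """
    if "lower_doy" not in records.columns:
        records = censor_records(records)
    table = records.merge(site_covariates, on="region_id", how="left", validate="m:1",
                          suffixes=("", "_site"))
    if covariate_columns is None:
        covariate_columns = [
            c for c in table.columns
            if c.startswith(("constancy_", "contingency_")) or c in ("elevation", "latitude")
        ]
    missing = table[covariate_columns].isna()
    if missing.to_numpy().any():
        col = missing.any()[missing.any()].index[0]
        rec = table.loc[missing[col], "record_id"].iloc[0] if "record_id" in table else "?"
        raise ValueError(f"missing covariate {col!r} for record {rec!r}")
    consts = []
    if standardize:
        for c in covariate_columns:
            x = table[c].to_numpy(float)
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            sd = sd if sd > 0 else 1.0
            table[c] = (x - mu) / sd
            consts.append({"covariate": c, "mean": mu, "sd": sd})
    constants = pd.DataFrame(consts, columns=["covariate", "mean", "sd"])
    return table, constants


def unstandardize(table: pd.DataFrame, constants: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`attach_covariates` standardization."""
    out = table.copy()
    for _, row in constants.iterrows():
        out[row["covariate"]] = out[row["covariate"]] * row["sd"] + row["mean"]
    return out
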