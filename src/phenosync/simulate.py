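"""Synthetic environmental series and birth-record populations.

Two generators make every pipeline stage testable without remote-sensing
downloads or the request-only fawn data:

* :func:`gen_environment` draws per-site daily climate and 8-day NDVI series
  from a seasonal sinusoid with interannual phase-free level shifts and iid
  noise, so the downstream predictability metrics are controllable (no
  noise, no shifts -> perfectly contingent; no seasonality -> constant).
* :func:`gen_population` is the exact forward model of the fitting
  likelihood: true birth day-of-year ~ Normal(x'beta + b_g, exp(z'gamma))
  with b_g ~ Normal(0, tau^2) per region x year, observed through an
  age-dependent back-calculation.  It returns the records plus a truth
  ledger for parameter-recovery tests.

The "paper_like" population preset mirrors the study's scale (16 regions,
~17,000 records, region mean dates spanning roughly day-of-year 129-161,
within-region SDs of 8-15 days); the "small" preset keeps the same
structure at ~2,000 records for routine testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import COLWELL_COVARIATES

#: per-variable seasonal process: base level, seasonal amplitude A, phase
#: (day of peak-aligned sine), interannual level-shift SD rho, daily noise SD
DEFAULT_ENV_PARAMS = {
    "temperature": {"base": 8.0, "amplitude": 9.0, "phase": 109.0, "rho": 0.8, "eps": 2.5},
    "precipitation": {"base": 2.5, "amplitude": 0.8, "phase": 280.0, "rho": 0.3, "eps": 2.0},
    "ndvi": {"base": 0.45, "amplitude": 0.30, "phase": 120.0, "rho": 0.03, "eps": 0.05},
}


@dataclass
class EnvScenario:
    sites: tuple = ("site_1",)
    year_start: int = 2001
    year_end: int = 2020
    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                  DEFAULT_ENV_PARAMS.items()})


def gen_environment(scenario: EnvScenario, seed: int) -> pd.DataFrame:
    """Long-format series (site_id, date, variable, value) for all sites.

    value(day) = base + A sin(2 pi (doy - phase)/365) + shift(year) + noise,
    with shift ~ N(0, rho^2) per year and noise ~ N(0, eps^2) per sample;
    NDVI is clipped to [-1, 1] and sampled at 8-day composite cadence,
    precipitation is truncated at zero, both climate variables are daily.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(scenario.year_start, scenario.year_end + 1)
    frames = []
    for site in scenario.sites:
        for var, p in scenario.params.items():
            cadence = 8 if var == "ndvi" else 1
            dates, values = [], []
            for y in years:
                shift = rng.normal(0.0, p["rho"]) if p["rho"] > 0 else 0.0
                n_days = pd.Timestamp(y, 12, 31).dayofyear
                doy = np.arange(1, n_days + 1, cadence)
                v = (p["base"]
                     + p["amplitude"] * np.sin(2 * np.pi * (doy - p["phase"]) / 365.0)
                     + shift)
                if p["eps"] > 0:
                    v = v + rng.normal(0.0, p["eps"], size=len(doy))
                if var == "ndvi":
                    v = np.clip(v, -1.0, 1.0)
                elif var == "precipitation":
                    v = np.clip(v, 0.0, None)
                dates.append(pd.to_datetime([f"{y}-01-01"]).repeat(len(doy))
                             + pd.to_timedelta(doy - 1, unit="D"))
                values.append(v)
            frames.append(pd.DataFrame({
                "site_id": site,
                "date": np.concatenate([d.values for d in dates]),
                "variable": var,
                "value": np.concatenate(values),
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# population generator


@dataclass
class PopScenario:
    """Forward-model configuration for a synthetic birth-record dataset.

    ``beta``/``gamma`` are coefficients on *z-scored* covariates (the ledger
    records the standardization constants actually used).  ``age_probs``
    gives the mix of estimated fawn ages over the three censoring classes
    (<=7, 8-14, >=15 days).
    """

    n_regions: int = 16
    n_total: int = 2000
    year_start: int = 2010
    year_end: int = 2019
    beta: dict = field(default_factory=lambda: {
        "intercept": 145.0, "elevation": 3.0, "latitude": 2.5,
        "contingency_ndvi": 2.0, "constancy_ndvi": -1.5,
        "contingency_precipitation": 0.5, "constancy_precipitation": -0.5,
        "contingency_temperature": 1.5, "constancy_temperature": -1.0,
    })
    gamma: dict = field(default_factory=lambda: {
        "intercept": np.log(10.0), "elevation": 0.06, "latitude": 0.04,
        "contingency_ndvi": -0.05, "constancy_ndvi": 0.03,
        "contingency_precipitation": 0.02, "constancy_precipitation": -0.02,
        "contingency_temperature": -0.04, "constancy_temperature": 0.02,
    })
    tau: float = 3.0
    age_probs: tuple = (0.6, 0.3, 0.1)
    within_region_covariate_sd: float = 0.35  # on the latent (pre-z-score) scale


def paper_like_scenario(**overrides) -> PopScenario:
    return PopScenario(n_total=17210, **overrides)


def small_scenario(**overrides) -> PopScenario:
    return PopScenario(n_total=2000, **overrides)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _region_covariates(rng: np.random.Generator, n_regions: int) -> pd.DataFrame:
    """Region-level covariate means with realistic cross-correlations.

    A Gaussian copula ties elevation negatively to temperature constancy and
    positively to NDVI contingency (mountain sites see stronger, more
    repeatable seasonality); latitude spans roughly the study's 43-61 deg N.
    """
    lat = np.sort(rng.uniform(43.0, 61.0, n_regions))
    lon = rng.uniform(-5.0, 25.0, n_regions)
    z_elev = rng.normal(0, 1, n_regions)
    rho = 0.5
    z_tcon = -rho * z_elev + np.sqrt(1 - rho**2) * rng.normal(0, 1, n_regions)
    z_ncont = rho * z_elev + np.sqrt(1 - rho**2) * rng.normal(0, 1, n_regions)
    elev = 150.0 + 1400.0 * _sigmoid(z_elev)
    cov = {
        "latitude": lat,
        "longitude": lon,
        "elevation": elev,
        "constancy_temperature": 0.15 + 0.5 * _sigmoid(z_tcon),
        "contingency_ndvi": 0.15 + 0.5 * _sigmoid(z_ncont),
    }
    for name in COLWELL_COVARIATES:
        if name not in cov:
            cov[name] = 0.15 + 0.5 * _sigmoid(rng.normal(0, 1, n_regions))
    cov["region_id"] = [f"R{i + 1:02d}" for i in range(n_regions)]
    return pd.DataFrame(cov)


def gen_population(scenario: PopScenario, seed: int):
    """Draw a birth-record table and its truth ledger.

    Returns ``(records, truth)``: records carry region/year/marking day/
    estimated age/coordinates/elevation plus the per-record covariates; the
    truth ledger holds the generating beta, gamma, tau (beta/gamma on the
    dataset's z-scored covariate scale), the region x year effects and each
    record's true (uncensored) birth day-of-year.
    """
    rng = np.random.default_rng(seed)
    regions = _region_covariates(rng, scenario.n_regions)
    years = np.arange(scenario.year_start, scenario.year_end + 1)

    # unbalanced region sizes: lognormal weights, at least a handful each
    w = rng.lognormal(0.0, 1.0, scenario.n_regions)
    n_region = np.maximum((w / w.sum() * scenario.n_total).round().astype(int), 25)

    cov_names = ["elevation", "latitude"] + list(COLWELL_COVARIATES)
    rows = []
    for r in range(scenario.n_regions):
        reg = regions.iloc[r]
        n_r = n_region[r]
        yr = rng.choice(years, n_r)
        rec = {
            "region_id": reg["region_id"],
            "year": yr,
            "latitude": reg["latitude"] + rng.normal(0, 0.08, n_r),
            "longitude": reg["longitude"] + rng.normal(0, 0.1, n_r),
            "elevation": np.clip(reg["elevation"]
                                 + rng.normal(0, 180.0, n_r), 0.0, None),
        }
        sd = scenario.within_region_covariate_sd
        for name in COLWELL_COVARIATES:
            rec[name] = np.clip(reg[name] + 0.2 * sd * rng.normal(0, 1, n_r),
                                0.0, 1.0)
        rows.append(pd.DataFrame(rec))
    df = pd.concat(rows, ignore_index=True)
    df["record_id"] = np.arange(len(df))

    # z-score covariates; beta/gamma act on this scale
    consts = []
    zcov = {}
    for c in cov_names:
        x = df[c].to_numpy(float)
        mu, s = x.mean(), x.std(ddof=0)
        s = s if s > 0 else 1.0
        zcov[c] = (x - mu) / s
        consts.append({"covariate": c, "mean": mu, "sd": s})

    mu = np.full(len(df), scenario.beta["intercept"])
    log_sigma = np.full(len(df), scenario.gamma["intercept"])
    for c in cov_names:
        mu += scenario.beta.get(c, 0.0) * zcov[c]
        log_sigma += scenario.gamma.get(c, 0.0) * zcov[c]

    group_key = df["region_id"].astype(str) + ":" + df["year"].astype(str)
    glabels, ginv = np.unique(group_key.to_numpy(), return_inverse=True)
    b = rng.normal(0.0, scenario.tau, len(glabels)) if scenario.tau > 0 else \
        np.zeros(len(glabels))
    true_doy = rng.normal(mu + b[ginv], np.exp(log_sigma))

    cls = rng.choice(3, len(df), p=scenario.age_probs)
    age = np.where(cls == 0, rng.integers(0, 8, len(df)),
                   np.where(cls == 1, rng.integers(8, 15, len(df)),
                            rng.integers(15, 26, len(df))))
    df["estimated_birth_doy"] = np.round(true_doy).astype(int)
    df["estimated_age_days"] = age
    df["marking_doy"] = df["estimated_birth_doy"] + age

    truth = {
        "beta": pd.Series({"intercept": scenario.beta["intercept"],
                           **{c: scenario.beta.get(c, 0.0) for c in cov_names}}),
        "gamma": pd.Series({"intercept": scenario.gamma["intercept"],
                            **{c: scenario.gamma.get(c, 0.0) for c in cov_names}}),
        "tau": scenario.tau,
        "group_effects": pd.Series(b, index=list(glabels)),
        "true_doy": true_doy,
        "standardization": pd.DataFrame(consts),
        "region_table": regions,
    }
    return df, truth


def gen_grid_covariates(n_points: int, seed: int, extent=(-10.0, 30.0, 40.0, 65.0)
                        ) -> pd.DataFrame:
    """Fabricate a grid covariate table with smooth spatial gradients."""
    rng = np.random.default_rng(seed)
    lon = rng.uniform(extent[0], extent[1], n_points)
    lat = rng.uniform(extent[2], extent[3], n_points)
    elev = np.clip(1200.0 * np.exp(-((lat - 46.0) ** 2) / 8.0)
                   + rng.normal(200.0, 120.0, n_points), 0.0, None)
    lon01 = (lon - extent[0]) / (extent[1] - extent[0])
    lat01 = (lat - extent[2]) / (extent[3] - extent[2])
    out = {"point_id": np.arange(n_points), "lon": lon, "lat": lat,
           "latitude": lat, "elevation": elev}
    out["contingency_temperature"] = np.clip(0.3 + 0.4 * lon01
                                             + rng.normal(0, 0.03, n_points), 0, 1)
    out["constancy_temperature"] = np.clip(0.6 - 0.35 * lon01
                                           + rng.normal(0, 0.03, n_points), 0, 1)
    out["contingency_ndvi"] = np.clip(0.25 + 0.3 * lon01 + 0.1 * lat01
                                      + rng.normal(0, 0.03, n_points), 0, 1)
    out["constancy_ndvi"] = np.clip(0.65 - 0.3 * lon01
                                    + rng.normal(0, 0.03, n_points), 0, 1)
    out["contingency_precipitation"] = np.clip(0.12 + rng.normal(0, 0.04, n_points), 0, 1)
    out["constancy_precipitation"] = np.clip(0.5 - 0.2 * lat01
                                             + rng.normal(0, 0.05, n_points), 0, 1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# recovery harness


def recovery_harness(scenario: PopScenario, preset: str, n_seeds: int,
                     base_seed: int = 0, compute_se: bool = True):
    """Generate -> prep -> fit -> score, repeated over seeds.

    Returns ``(per_coefficient_summary, per_seed_table)``: bias, RMSE and
    (if SEs are computed) coverage of +-2 SE intervals for each location
    coefficient, plus recovery of the baseline scale exp(gamma_0) and tau.
    Non-convergent fits are counted, not raised.
    """
    from . import records as rp
    from .model import ModelSpec, fit as fit_model

    if isinstance(preset, ModelSpec):
        spec = preset
    elif preset == "full":
        # well-specified: every covariate the forward model uses
        covs = ("elevation", "latitude") + tuple(COLWELL_COVARIATES)
        spec = ModelSpec(name="full", location_covariates=covs, scale_covariates=covs)
    else:
        spec = ModelSpec.preset(preset)
    per_seed = []
    n_fail = 0
    for k in range(n_seeds):
        seed = base_seed + k
        df, truth = gen_population(scenario, seed)
        table, consts = rp.attach_covariates(
            rp.censor_records(df), truth["region_table"][["region_id"]],
            covariate_columns=["elevation", "latitude"] + list(COLWELL_COVARIATES))
        try:
            f = fit_model(spec, table, compute_se=compute_se, seed=seed)
        except Exception:
            n_fail += 1
            continue
        if not f.converged:
            n_fail += 1
        row = {"seed": seed, "converged": f.converged, "tau_hat": f.tau,
               "tau_true": truth["tau"],
               "sigma0_hat": float(np.exp(f.gamma["intercept"])),
               "sigma0_true": float(np.exp(truth["gamma"]["intercept"]))}
        for name, est in f.beta.items():
            row[f"beta_{name}"] = est
            row[f"beta_{name}_true"] = truth["beta"].get(name, 0.0)
            if compute_se and f.se_beta is not None:
                row[f"beta_{name}_se"] = f.se_beta[name]
        per_seed.append(row)
    ps = pd.DataFrame(per_seed)
    summary = []
    if not ps.empty:
        beta_names = [c[5:] for c in ps.columns
                      if c.startswith("beta_") and not c.endswith(("_true", "_se"))]
        for name in beta_names:
            err = ps[f"beta_{name}"] - ps[f"beta_{name}_true"]
            row = {"coefficient": name, "bias": err.mean(),
                   "rmse": float(np.sqrt((err**2).mean()))}
            se_col = f"beta_{name}_se"
            if se_col in ps.columns:
                cov = (np.abs(err) <= 2.0 * ps[se_col]).mean()
                row["coverage_2se"] = float(cov)
            summary.append(row)
        err_s = ps["sigma0_hat"] - ps["sigma0_true"]
        summary.append({"coefficient": "sigma0", "bias": err_s.mean(),
                        "rmse": float(np.sqrt((err_s**2).mean()))})
        err_t = ps["tau_hat"] - ps["tau_true"]
        summary.append({"coefficient": "tau", "bias": err_t.mean(),
                        "rmse": float(np.sqrt((err_t**2).mean()))})
    return pd.DataFrame(summary), ps, n_fail
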