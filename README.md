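# phenosync

Tools for studying how the **timing and synchrony of ungulate births** track
the **predictability of the environment**. The package was built around the
reproductive phenology of European roe deer (*Capreolus capreolus*), an
income breeder whose fawning season is under strong selection to match the
spring vegetation flush, but every stage is generic: any georeferenced
birth-record table plus per-site environmental time series will do.

It provides, as a Python library and a `phenosync` command line tool:

1. **Environmental predictability** — Colwell's entropy-based metrics from
   climate and NDVI series. For a variable tabulated into states
   *i* = 1..*s* over within-year time classes *j* = 1..*t* across years,
   with column totals *X*<sub>j</sub>, row totals *Y*<sub>i</sub> and grand
   total *Z*,

   - constancy  C = 1 − H(Y)/log *s*
   - contingency M = (H(X) + H(Y) − H(XY))/log *s*
   - predictability P = C + M

   where H(·) are Shannon entropies of the corresponding marginal/joint
   frequencies. C = 1 means the variable is flat across the year;
   M = 1 means a seasonal pattern that repeats identically every year.

2. **Record preparation** — back-calculated birth dates become
   interval-censored observations [birth − δ, birth + δ] with δ = 2, 3 or 5
   days for fawns estimated ≤ 7, 8–14 or ≥ 15 days old, and regions whose
   fawn searches drifted earlier over the years (a search-effort artefact)
   are flagged by a bootstrap quantile-regression trend screen.

3. **Interval-censored Gaussian location-scale regression** — both the mean
   date μ (identity link) and the scale σ (log link) are regressed on
   covariates, with a Gaussian region×year random intercept integrated out
   of the marginal likelihood by a Laplace approximation:

   μᵢ = xᵢ′β + b_g,  log σᵢ = zᵢ′γ,  b_g ~ N(0, τ²),
   ℓᵢ = log[Φ((uᵢ−μᵢ)/σᵢ) − Φ((lᵢ−μᵢ)/σᵢ)].

   Birth synchrony is reported as the central 80% interval width,
   2.5631·σ. Four model presets are built in (null / latitude-elevation /
   colwell-elevation / colwell-only) plus AIC-based comparison.

4. **Spatial prediction and validation** — equally spaced point grids
   (azimuthal-equidistant spacing in km, not degrees), phenology surfaces
   with min/mean/max/std summaries, per-region elevation classes, and
   validation of predictions against published regional birth distributions
   with an MAE summary.

5. **Synthetic data** — generators for environmental series with
   controllable predictability and for birth-record populations drawn from
   the exact model the fitter assumes, with a truth ledger for
   parameter-recovery studies.

## Worked example

```python
import numpy as np
import phenosync as ps
import phenosync.records as rp

# a small synthetic population: 16 regions, ~2,000 records, known truth
records, truth = ps.gen_population(ps.small_scenario(), seed=42)
table, consts = rp.attach_covariates(
    rp.censor_records(records), records[["region_id"]].drop_duplicates(),
    covariate_columns=["elevation", "latitude"] + list(ps.COLWELL_COVARIATES))

fit = ps.fit(ps.ModelSpec.preset("latitude_elevation"), table,
             standardization=consts)
print(round(fit.beta["intercept"], 2), round(np.exp(fit.gamma["intercept"]), 2),
      round(fit.tau, 2))
# 145.18 10.3 3.58

p = ps.predict(fit, {"latitude": 0.0, "elevation": 0.0})
print(round(p.mu, 1), round(p.synchrony80, 1))
# 145.2 26.4
```

The fitted intercept is the mean parturition day-of-year at average
covariates (~25 May), `exp(γ₀)` the baseline scale in days, `tau` the SD of
the region×year annual fluctuations, and `synchrony80` the window expected
to contain the central 80% of births (days).

The same analysis runs from the shell:

```sh
phenosync simulate --scenario small --seed 42 --out run/
phenosync colwell --series run/series.csv --out run/metrics.csv
phenosync prep --records run/records.csv --qc --seed 17 --out run/
phenosync fit --table run/model_table.csv --model colwell_elevation --out run/
phenosync run --config config.yaml      # everything from one file
```

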