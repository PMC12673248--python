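# Methods

## Environmental predictability (Colwell's metrics)

Per site and variable, the raw series is reduced to a years × time-class
matrix: NDVI to 12 monthly means, temperature to 52 weekly means,
precipitation to 52 weekly totals. Weeks are fixed 7-day blocks counted
from 1 January; the one or two leftover days at the end of each year are
dropped so every weekly cell covers exactly 7 days (folding them into a
long week 52 would make a constant daily series look non-constant in its
weekly totals). NDVI composites are smoothed beforehand with a
Savitzky–Golay filter whose window is specified physically (45 days,
polynomial order 2) and converted to the nearest odd number of sample
points given the series cadence — 5 points at the 8-day composite cadence —
floored at `polyorder + 2`.

Matrix cells are binned into *s* states (default 11) spanning the observed
range at that site. Equal-width binning is the default because it preserves
the physical meaning of a "state" for continuous variables; equal-frequency
binning is available for sensitivity checks and falls back to an
equal-width grid when ties collapse the quantiles. All bins are half-open
except the top, which is closed so the maximum value is counted once.
A numerically constant matrix (range below 1e-12 relative) is treated as
exactly constant rather than having floating-point jitter stretched across
the grid. Missing cells are excluded from the counts (the grand total
shrinks) and a completeness fraction is reported; nothing is imputed.

Entropies use natural logarithms; the normalisation by log *s* makes
constancy, contingency and predictability log-base invariant. The number of
states, binning strategy and smoothing parameters are recorded in the
pipeline's metadata sidecar because the metrics' absolute values depend on
them.

## Interval censoring and the sampling-onset screen

Fawn ages are estimated, so back-calculated birth dates carry age-dependent
uncertainty. Each record becomes the interval [birth − δ, birth + δ] with
δ = 2 days for estimated age ≤ 7 days, 3 days for 8–14, 5 days for ≥ 15.
The class boundaries are closed downwards (age exactly 7 → ±2, age exactly
15 → ±5). Intervals live on a continuous day-of-year axis with no year-end
wrap; roe deer births in these data never straddle the year boundary.

Because part of the data is collected by volunteer searches whose onset can
drift earlier for reasons unrelated to deer (mowing schedules), each region
is screened by quantile regressions of marking day on year at the 0.1, 0.5
and 0.9 quantiles. Slopes come from statsmodels' pinball-loss fit;
p-values from a seeded case-resampling bootstrap of (year, day) pairs
(default B = 1000), with the bootstrap refits done by a vectorised IRLS
solver for speed. Only significantly *negative* trends (earlier searches
over time) trigger exclusion, and because three quantiles are tested per
region the decision uses Bonferroni-adjusted p-values so the familywise
false-exclusion rate is held at α = 0.05 (measured at 3% over 100 null
datasets, with 10/10 detection of a 2 day/year median drift at noise SD 5
and 300 records).

## The interval-censored location-scale model

Both distribution parameters of the Gaussian response are structured:
μᵢ = xᵢ′β + b_g (identity link, days) and log σᵢ = zᵢ′γ, with a scalar
random intercept b_g ~ N(0, τ²) per region×year group on the location
predictor only — the standard placement, identifiable with modest group
counts. The presets give location and scale the same covariate list.
Covariates are z-scored before fitting (constants stored for
back-transformation), so β is in days per SD of covariate.

Each observation contributes log[Φ((u−μ)/σ) − Φ((l−μ)/σ)]; exact
observations (l = u) contribute the log density. The CDF difference is
evaluated on whichever normal tail keeps the operands small, via
`log_ndtr` and a stable log(1 − e^x), so intervals 16+ SDs out remain
finite and accurate. σ is floored at 1e-6 days with a warning.

Random intercepts are integrated out by a Laplace approximation. The inner
maximisation over all group intercepts runs as one vectorised, damped
Newton iteration (the interval-normal log-likelihood is concave in μ, so
the joint objective is strictly concave and the mode unique); an adaptive
9-node Gauss–Hermite quadrature centred on the Laplace mode is available as
an accuracy cross-check and agrees to ~1e-5 on realistic fits. The outer
optimisation is L-BFGS-B over (β, γ, log τ) with finite-difference
gradients, gradient tolerance 1e-7, ftol 1e-11, 500 iterations, log τ
bounded in [log 1e-3, log 200], and one seeded, perturbed restart on
non-convergence. Initialisation: β from an ordinary least-squares fit of
the interval midpoints on the location design (this generalises the
mean-midpoint intercept start to designs with region indicators and halves
the fit time of the dummy-rich null preset), γ intercept at the log
residual SD, other γ at 0, log τ at log 5.

AIC counts fixed effects plus one parameter for τ; random-effect modes are
not counted (marginal-likelihood convention). Model comparison reports raw
log-likelihoods and signed deltas (fit − reference) for both loglik and
AIC. Predictions are conditional at the random-effect mean (b = 0);
synchrony is the central 80% interval width (z₀.₉ − z₀.₁)·σ = 2.5631·σ.

## Spatial prediction

"Equally spaced" grids are built in a spherical azimuthal-equidistant
projection centred on the extent midpoint (mean Earth radius 6371.0088 km)
— spacing is a physical distance, not a degree step. The point lattice is
centred symmetrically on the projected bounding box of the densified extent
boundary, so an extent spanning ~100 km at 50 km spacing yields 3 × 3
points, and back-projected to lon/lat; an optional polygon mask (GeoJSON or
shapely) drops outside points. Per-region elevation classes use
linear-interpolation (type-7) percentiles: the 10th percentile, the mean of
records between the 45th and 55th percentiles, and the 90th percentile.

## Validation

Predictions are scored against a packaged table of published regional birth
distributions (mean day-of-year and 80% synchrony where reported, with the
two published model predictions alongside). Sites with known n ≤ 30 are
excluded; sites with unknown n are retained and logged; a site missing one
reported quantity contributes only to the other MAE. Differences are
predicted − reported.

## Synthetic data

`gen_environment` draws value(day) = base + A·sin(2π(day − phase)/365) +
yearshift(ρ) + noise(ε): temperature daily (base 8 °C, A 9, ρ 0.8, ε 2.5),
precipitation daily truncated at zero (base 2.5 mm, A 0.8, ρ 0.3, ε 2.0),
NDVI at 8-day cadence clipped to [−1, 1] (base 0.45, A 0.30, ρ 0.03,
ε 0.05) — values chosen to mimic mid-latitude European seasonality with
strongly seasonal temperature/NDVI and weakly seasonal precipitation. A
flat, noise-free scenario is perfectly constant downstream (C = 1, M = 0);
a noise-free seasonal one is maximally contingent for the binning used.

`gen_population` is the exact forward model of the fitting likelihood:
region-level covariates are drawn with a Gaussian copula tying elevation
negatively to temperature constancy and positively to NDVI contingency
(ρ = 0.5, mimicking mountain climates), latitudes span 43–61° N, and each
record adds within-region covariate scatter — as in the real pipeline,
where predictability metrics are computed per birth location. True dates
are Normal(x′β + b_g, exp(z′γ)) with b_g ~ N(0, τ²); defaults: intercept
day 145, elevation +3 d/SD, latitude +2.5 d/SD, smaller predictability
effects, baseline σ = 10 days, τ = 3 days. Estimated ages mix 60% ≤ 7 d,
30% 8–14 d, 10% ≥ 15 d; marking day = rounded true date + age, so with
exact ages the censoring interval always contains the back-calculated date.
The "paper-like" preset draws ~17,000 records over 16 unbalanced regions;
the "small" preset (~2,000) is the test default and is what the recovery
and model-comparison studies use (10 recovery seeds; 25 comparison
replicates at n = 600), sizes chosen to give the Monte-Carlo checks clear
margins at desk runtime.

What the generator does **not** emulate: spatial rasters and their
extraction error, cloud contamination of NDVI, observer heterogeneity
beyond the age-class mix, and any misspecification of the Gaussian
response — so passing recovery tests demonstrates correctness of the
estimator under its own assumptions, not robustness of those assumptions
for field data.

## Known limitations

- The Laplace approximation can bias τ̂ slightly for very small groups;
  the Gauss–Hermite cross-check bounds this in practice.
- Quantile-regression bootstrap p-values are approximate for the extreme
  quantiles when few distinct years exist.
- The spherical projection ignores ellipsoidal flattening (~0.3% distance
  error), immaterial at 50 km grid spacing.
- Colwell metrics depend on the discretisation (s, strategy); only
  comparisons made with identical settings are meaningful.
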