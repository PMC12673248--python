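"""Interval-censored location-scale model: likelihood, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

import phenosync as ps
import phenosync.records as rp
from phenosync.model import (
    ModelSpec,
    SYNCHRONY80_FACTOR,
    _prepare_data,
    interval_normal_loglik,
    marginal_loglik,
)


# ---------------------------------------------------------------------------
# likelihood kernel


def test_unbounded_interval_contributes_zero():
    ll = interval_normal_loglik([-np.inf], [np.inf], 140.0, 10.0)
    assert ll[0] == pytest.approx(0.0, abs=1e-12)


def test_worked_interval_against_cdf_oracle():
    ll = interval_normal_loglik([138.0], [142.0], 140.0, 10.0)
    oracle = np.log(norm.cdf(0.2) - norm.cdf(-0.2))
    assert ll[0] == pytest.approx(oracle, abs=1e-10)
    assert ll[0] == pytest.approx(-1.842, abs=1e-3)


def test_likelihood_matches_numeric_integration():
    rng = np.random.default_rng(2)
    for _ in range(100):
        mu = rng.uniform(100, 180)
        sigma = rng.uniform(2, 20)
        lo = rng.uniform(mu - 4 * sigma, mu + 3 * sigma)
        hi = lo + rng.uniform(0.5, 15)
        ll = interval_normal_loglik([lo], [hi], mu, sigma)[0]
        num, _ = integrate.quad(lambda x: norm.pdf(x, mu, sigma), lo, hi,
                                epsabs=1e-14, epsrel=1e-12)
        assert ll == pytest.approx(np.log(num), abs=1e-8)


def test_far_tail_interval_is_finite_and_accurate():
    # interval 16-16.5 SDs out: naive CDF differencing underflows
    ll = interval_normal_loglik([300.0], [305.0], 140.0, 10.0)[0]
    assert np.isfinite(ll)
    from scipy.special import log_ndtr
    oracle = log_ndtr(-16.0) + np.log1p(-np.exp(log_ndtr(-16.5) - log_ndtr(-16.0)))
    assert ll == pytest.approx(oracle, rel=1e-10)


def test_symmetric_interval_maximized_at_midpoint():
    mus = np.linspace(130, 150, 201)
    lls = [interval_normal_loglik([138.0], [142.0], m, 10.0)[0] for m in mus]
    assert mus[int(np.argmax(lls))] == pytest.approx(140.0, abs=0.1)


def test_exact_observation_uses_log_density():
    ll = interval_normal_loglik([140.0], [140.0], 140.0, 10.0)
    assert ll[0] == pytest.approx(norm.logpdf(140, 140, 10))


def test_sigma_floor_warns():
    with pytest.warns(UserWarning, match="floored"):
        interval_normal_loglik([138.0], [142.0], 140.0, 1e-9)


def test_conditional_loglik_with_group_effects():
    data = {"lower": np.array([138.0, 148.0]), "upper": np.array([142.0, 152.0]),
            "X": np.ones((2, 1)), "Z": np.zeros((2, 1)), "groups": np.array([0, 1])}
    ll = ps.loglik_interval_normal([140.0], [np.log(10.0) * 0.0], data,
                                   group_effects=[0.0, 10.0])
    by_hand = (interval_normal_loglik([138.0], [142.0], 140.0, 1.0)[0]
               + interval_normal_loglik([148.0], [152.0], 150.0, 1.0)[0])
    assert ll == pytest.approx(by_hand)


# ---------------------------------------------------------------------------
# fitting


def _intercept_table(rng, n, mu, sigma, half=2.0):
    doy = rng.normal(mu, sigma, n)
    return pd.DataFrame({
        "region_id": "A", "year": 2010,
        "lower_doy": doy - half, "upper_doy": doy + half,
    })


def test_intercept_only_mle_recovers_truth():
    rng = np.random.default_rng(0)
    table = _intercept_table(rng, 5000, 145.0, 10.0)
    spec = ModelSpec(name="intercept", location_covariates=(),
                     scale_covariates=(), random_effect=None)
    f = ps.fit(spec, table)
    assert f.beta["intercept"] == pytest.approx(145.0, abs=0.3)
    assert np.exp(f.gamma["intercept"]) == pytest.approx(10.0, abs=0.4)
    assert f.converged


def test_zero_tau_data_estimates_small_tau(model_table):
    # ~90 records per region x year group give the boundary MLE enough
    # information to collapse towards zero
    scen = ps.PopScenario(n_total=3000, tau=0.0, year_start=2010, year_end=2011,
                          beta={"intercept": 145.0, "elevation": 3.0},
                          gamma={"intercept": np.log(10.0)})
    df, _ = ps.gen_population(scen, 4)
    table, _ = rp.attach_covariates(
        rp.censor_records(df), df[["region_id"]].drop_duplicates(),
        covariate_columns=["elevation"])
    spec = ModelSpec(name="elev", location_covariates=("elevation",),
                     scale_covariates=("elevation",))
    f = ps.fit(spec, table)
    assert f.tau < 0.5


def test_group_modes_average_near_zero(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("latitude_elevation"), table)
    assert f.tau > 0
    assert abs(f.group_modes.mean()) < 1.0


def test_irrelevant_covariate_never_hurts_loglik_and_costs_aic():
    wins = 0
    n_rep = 20
    for k in range(n_rep):
        rng = np.random.default_rng(100 + k)
        table = _intercept_table(rng, 300, 145.0, 10.0)
        table["noise"] = rng.normal(0, 1, len(table))
        base = ps.fit(ModelSpec(name="base", location_covariates=(),
                                scale_covariates=(), random_effect=None), table)
        bigger = ps.fit(ModelSpec(name="plus", location_covariates=("noise",),
                                  scale_covariates=(), random_effect=None), table,
                        init=np.insert(np.concatenate(
                            [base.beta.values, base.gamma.values]), 1, 0.0))
        assert bigger.loglik >= base.loglik - 1e-6
        if bigger.aic > base.aic:
            wins += 1
    # chi-square(1) oracle: AIC rises unless 2*delta-loglik > 2, i.e. with
    # probability P(chi2_1 < 2) = 0.843; check the empirical rate is
    # consistent at ~2.5 binomial SDs
    expected = 0.8427
    band = 2.5 * np.sqrt(expected * (1 - expected) / n_rep)
    assert abs(wins / n_rep - expected) <= band


def test_shift_equivariance():
    rng = np.random.default_rng(6)
    table = _intercept_table(rng, 800, 145.0, 10.0)
    spec = ModelSpec(name="i", location_covariates=(), scale_covariates=(),
                     random_effect=None)
    f0 = ps.fit(spec, table)
    shifted = table.copy()
    shifted["lower_doy"] += 30.0
    shifted["upper_doy"] += 30.0
    f1 = ps.fit(spec, shifted)
    assert f1.beta["intercept"] == pytest.approx(f0.beta["intercept"] + 30.0, abs=1e-3)
    assert f1.gamma["intercept"] == pytest.approx(f0.gamma["intercept"], abs=1e-4)


def test_scale_consistency():
    rng = np.random.default_rng(8)
    table = _intercept_table(rng, 800, 145.0, 10.0)
    spec = ModelSpec(name="i", location_covariates=(), scale_covariates=(),
                     random_effect=None)
    f0 = ps.fit(spec, table)
    doubled = table.copy()
    doubled["lower_doy"] *= 2.0
    doubled["upper_doy"] *= 2.0
    f1 = ps.fit(spec, doubled)
    assert np.exp(f1.gamma["intercept"]) == pytest.approx(
        2.0 * np.exp(f0.gamma["intercept"]), rel=1e-3)


def test_widening_intervals_changes_scale_estimate():
    # the fit must respond to interval width, not just midpoints
    rng = np.random.default_rng(10)
    doy = rng.normal(145, 10.0, 2000)
    spec = ModelSpec(name="i", location_covariates=(), scale_covariates=(),
                     random_effect=None)
    sigmas = {}
    for half in (2.0, 5.0):
        t = pd.DataFrame({"region_id": "A", "year": 2010,
                          "lower_doy": doy - half, "upper_doy": doy + half})
        sigmas[half] = float(np.exp(ps.fit(spec, t).gamma["intercept"]))
    change = abs(sigmas[5.0] - sigmas[2.0])
    assert 0.02 < change < 3.0


def test_rank_deficient_design_is_rejected():
    rng = np.random.default_rng(12)
    table = _intercept_table(rng, 100, 145.0, 10.0)
    table["a"] = rng.normal(0, 1, 100)
    table["b"] = 2.0 * table["a"]
    spec = ModelSpec(name="bad", location_covariates=("a", "b"),
                     scale_covariates=(), random_effect=None)
    with pytest.raises(ValueError, match="rank"):
        ps.fit(spec, table)


def test_laplace_agrees_with_gauss_hermite(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("latitude_elevation"), table)
    data, *_ = _prepare_data(ModelSpec.preset("latitude_elevation"), table)
    theta = np.concatenate([f.beta.values, f.gamma.values, [np.log(f.tau)]])
    lap = marginal_loglik(theta, data, 3, 3, method="laplace")
    gh = marginal_loglik(theta, data, 3, 3, method="gh9")
    assert lap == pytest.approx(gh, abs=0.05)


# ---------------------------------------------------------------------------
# prediction


def test_prediction_at_covariate_means(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("colwell_elevation"), table)
    row = {c: 0.0 for c in f.beta.index if c != "intercept"}
    p = ps.predict(f, row)
    assert p.mu == pytest.approx(f.beta["intercept"])
    assert p.sigma == pytest.approx(np.exp(f.gamma["intercept"]))


def test_synchrony_is_80pct_interval_width():
    p = ps.PredictionResult(mu=145.0, sigma=10.0)
    assert p.synchrony80 == pytest.approx(2.5631032 * 10.0, abs=1e-5)
    assert SYNCHRONY80_FACTOR == pytest.approx(norm.ppf(0.9) - norm.ppf(0.1), abs=1e-12)


def test_prediction_monotone_in_positive_covariate(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("latitude_elevation"), table)
    lo = ps.predict(f, {"latitude": 0.0, "elevation": 0.0})
    hi = ps.predict(f, {"latitude": 0.0, "elevation": 1.0})
    assert (hi.mu > lo.mu) == (f.beta["elevation"] > 0)
    assert hi.mu - lo.mu == pytest.approx(f.beta["elevation"])


def test_unknown_covariate_in_prediction_errors(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("latitude_elevation"), table)
    with pytest.raises(ValueError, match="unknown covariate"):
        ps.predict(f, {"latitude": 0.0})


# ---------------------------------------------------------------------------
# comparison


def test_compare_with_self_is_zero(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("colwell_only"), table)
    cmp = ps.compare([f], reference=f)
    assert cmp["delta_loglik"].iloc[0] == 0.0
    assert cmp["delta_AIC"].iloc[0] == 0.0


def test_nested_model_loglik_monotone(model_table):
    table, consts, truth = model_table
    small = ps.fit(ModelSpec.preset("colwell_only"), table)
    # warm-start the larger model from the smaller one's solution
    p_small = len(small.beta)
    init = np.concatenate([small.beta.values, [0.0], small.gamma.values, [0.0],
                           [np.log(max(small.tau, 1e-3))]])
    big = ps.fit(ModelSpec.preset("colwell_elevation"), table, init=init)
    assert big.loglik >= small.loglik - 1e-6
    cmp = ps.compare([small, big], reference=small)
    assert cmp.loc[1, "delta_loglik"] >= -1e-6


def test_compare_rejects_mismatched_observation_sets(model_table):
    table, consts, truth = model_table
    f1 = ps.fit(ModelSpec.preset("colwell_only"), table)
    f2 = ps.fit(ModelSpec.preset("colwell_only"), table.iloc[:500])
    with pytest.raises(ValueError, match="observation set"):
        ps.compare([f1, f2])


def test_aic_definition(model_table):
    table, consts, truth = model_table
    f = ps.fit(ModelSpec.preset("latitude_elevation"), table)
    assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
    # fixed effects on both parameters plus the random-intercept SD
    assert f.n_params == 3 + 3 + 1
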