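"""Posterior-predictive probabilities, durations, IQR and KS distance."""

import numpy as np
import pytest
from scipy import stats

from lineagefate.prediction import (
    duration_quartiles_iqr,
    ks_distance,
    mn_fold_change,
    predict_mn_prob,
    predictive_duration_samples,
)
from lineagefate.sampler import PosteriorDraws
from lineagefate.specs import get_spec


def _point_posterior(names, values, reps=1):
    """A degenerate posterior: `reps` identical draws."""
    arr = np.tile(np.asarray(values, float), (1, reps, 1))
    return PosteriorDraws(names=list(names), draws=arr, log_lik=np.zeros((reps, 1)),
                          lineage_draws=None, metadata={"rhat": {}, "warnings": []})


MN_SPEC = get_spec("1_4")
DUR_SPEC = get_spec("2_4")  # micro-only log-normal, sigma by condition


def test_point_posterior_reproduces_study_probabilities():
    draws = _point_posterior(["b", "scf"], [[-4.575, 2.44]])
    q0 = predict_mn_prob(draws, MN_SPEC, {"scf": 0})
    q1 = predict_mn_prob(draws, MN_SPEC, {"scf": 1})
    assert abs(q0["average"] - 0.0102) < 2e-4
    assert abs(q1["average"] - 0.106) < 1e-3
    fc = mn_fold_change(draws, MN_SPEC, {"scf": 1}, {"scf": 0})
    assert abs(fc["fold_change"] - 10.39) < 0.05


def test_all_zero_coefficients_give_half():
    draws = _point_posterior(["b", "scf"], [[0.0, 0.0]], reps=5)
    out = predict_mn_prob(draws, MN_SPEC, {"scf": 1})
    assert np.all(out["samples"] == 0.5)


def test_fold_change_of_identical_covariates_is_one():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(1, 20, 2))
    draws = PosteriorDraws(names=["b", "scf"], draws=vals, log_lik=np.zeros((20, 1)),
                           lineage_draws=None, metadata={"rhat": {}, "warnings": []})
    fc = mn_fold_change(draws, MN_SPEC, {"scf": 1}, {"scf": 1})
    assert np.isclose(fc["fold_change"], 1.0, rtol=1e-12)


def test_small_probability_limit_matches_odds_ratio():
    # with a tiny baseline, probability ratio -> odds ratio = exp(scf)
    draws = _point_posterior(["b", "scf"], [[-12.0, np.log(4.0)]])
    fc = mn_fold_change(draws, MN_SPEC, {"scf": 1}, {"scf": 0})
    assert abs(fc["fold_change"] - 4.0) < 1e-3


def test_unknown_covariate_rejected():
    draws = _point_posterior(["b", "scf"], [[0.0, 1.0]])
    with pytest.raises(KeyError):
        predict_mn_prob(draws, MN_SPEC, {"rnf": 1})


def test_predictive_probability_bounded_by_draw_range():
    rng = np.random.default_rng(1)
    vals = np.stack([rng.normal(-4, 0.3, 50), rng.normal(2.4, 0.2, 50)], axis=1)[None]
    draws = PosteriorDraws(names=["b", "scf"], draws=vals, log_lik=np.zeros((50, 1)),
                           lineage_draws=None, metadata={"rhat": {}, "warnings": []})
    out = predict_mn_prob(draws, MN_SPEC, {"scf": 1})
    assert out["samples"].min() <= out["average"] <= out["samples"].max()


def _dur_draws(mu=np.log(17.0), micro=0.82, sigma=0.3):
    return _point_posterior(["b", "micro", "sigma[0]"], [[mu, micro, sigma]])


def test_sigma_to_zero_collapses_to_median():
    draws = _dur_draws(sigma=1e-12)
    s = predictive_duration_samples(draws, DUR_SPEC, {}, mn_status=0, m=50, seed=0)
    assert np.allclose(s, 17.0, rtol=1e-6)


def test_micro_toggle_multiplies_median_by_exp_micro():
    draws = _dur_draws()
    s0 = predictive_duration_samples(draws, DUR_SPEC, {}, mn_status=0, m=100_000, seed=1)
    s1 = predictive_duration_samples(draws, DUR_SPEC, {}, mn_status=1, m=100_000, seed=2)
    ratio = np.median(s1) / np.median(s0)
    assert abs(ratio - np.exp(0.82)) < 0.05
    assert round(float(np.exp(0.82)), 2) == 2.27


def test_quartiles_match_lognormal_closed_form():
    draws = _dur_draws(sigma=0.3)
    s = predictive_duration_samples(draws, DUR_SPEC, {}, mn_status=0, m=100_000, seed=3)
    q = duration_quartiles_iqr(s)
    z = stats.norm.ppf(0.75)  # 0.6745
    assert abs(q["q25"] - 17 * np.exp(-z * 0.3)) < 0.15
    assert abs(q["q75"] - 17 * np.exp(z * 0.3)) < 0.15
    assert abs(q["iqr"] - (17 * np.exp(z * 0.3) - 17 * np.exp(-z * 0.3))) < 0.25


def test_quartiles_linear_interpolation_convention():
    q = duration_quartiles_iqr([1.0, 2.0, 3.0, 4.0])
    assert (q["q25"], q["q50"], q["q75"], q["iqr"]) == (1.75, 2.5, 3.25, 1.5)
    assert duration_quartiles_iqr([5.0] * 10)["iqr"] == 0.0


def test_iqr_scales_linearly():
    rng = np.random.default_rng(7)
    s = rng.lognormal(np.log(17), 0.3, 5000)
    for k in (0.5, 3.0):
        assert np.isclose(duration_quartiles_iqr(k * s)["iqr"],
                          k * duration_quartiles_iqr(s)["iqr"], rtol=1e-9)


def test_ks_identical_and_disjoint():
    x = np.arange(10.0)
    assert ks_distance(x, x)["D"] == 0.0
    assert ks_distance(x, x + 100.0)["D"] == 1.0


def test_ks_matches_numeric_cdf_difference():
    # LogNormal(ln 17, .3) vs LogNormal(ln 17 + .82, .3): sup distance of
    # two normals with equal sd shifted by .82/.3 sds
    rng = np.random.default_rng(8)
    a = rng.lognormal(np.log(17), 0.3, 50_000)
    b = rng.lognormal(np.log(17) + 0.82, 0.3, 50_000)
    grid = np.linspace(np.log(5), np.log(120), 4001)
    d_true = np.max(np.abs(stats.norm.cdf(grid, np.log(17), 0.3)
                           - stats.norm.cdf(grid, np.log(17) + 0.82, 0.3)))
    out = ks_distance(a, b)
    assert abs(out["D"] - d_true) < 0.01
    assert out["p_value"] < 1e-10
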