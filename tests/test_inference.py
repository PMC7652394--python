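"""Sampler correctness against conjugate oracles, and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from lineagefate.design import ModelData
from lineagefate.diagnostics import ess, rhat, summarize
from lineagefate.sampler import PosteriorDraws, sample_posterior
from lineagefate.simulate import inv_logit
from lineagefate.specs import ModelSpec


def _mn_data(mn):
    n = len(mn)
    return ModelData(
        X=np.zeros((n, 4)), mn=np.asarray(mn, int), duration=np.full(n, np.nan),
        duration_mask=np.zeros(n, bool), lineage_idx=np.zeros(n, int),
        condition_idx=np.zeros(n, int), lineage_ids=["L0"],
        conditions=[("CTRL48", "mCit", "N+x")],
    )


def _duration_data(y):
    n = len(y)
    return ModelData(
        X=np.zeros((n, 4)), mn=np.zeros(n, int), duration=np.asarray(y, float),
        duration_mask=np.ones(n, bool), lineage_idx=np.zeros(n, int),
        condition_idx=np.zeros(n, int), lineage_ids=["L0"],
        conditions=[("CTRL48", "mCit", "N+x")],
    )


_MN0 = ModelSpec("mn_intercept", "MN", "bernoulli_logit", ())
_DUR0 = ModelSpec("dur_intercept", "interphase_duration", "lognormal", ("micro",),
                  sigma_grouping="shared")


def test_binomial_posterior_matches_beta_oracle():
    # k = 20 of n = 100 events; under a flat-ish prior on the logit, the
    # posterior of inv_logit(b) is close to Beta(k + 1/2, n - k + 1/2)
    k, n = 20, 100
    data = _mn_data([1] * k + [0] * (n - k))
    draws = sample_posterior(_MN0, data, chains=4, iterations=3000, warmup=1000, seed=0)
    p = inv_logit(draws.get("b"))
    beta = stats.beta(k + 0.5, n - k + 0.5)
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        assert abs(np.quantile(p, q) - beta.ppf(q)) < 0.02


def test_lognormal_intercept_matches_normal_conjugate():
    rng = np.random.default_rng(5)
    mu_true, sigma = np.log(17.0), 0.25
    y = np.exp(rng.normal(mu_true, sigma, size=300))
    data = _duration_data(y)
    draws = sample_posterior(_DUR0, data, chains=4, iterations=2000, warmup=1000, seed=1)
    b = draws.get("b")
    # known-sigma conjugate posterior: N(m, v) with prior N(0, 10^2)
    logy = np.log(y)
    v = 1.0 / (len(y) / sigma**2 + 1.0 / 100.0)
    m = v * logy.sum() / sigma**2
    assert abs(b.mean() - m) < 4 * np.sqrt(v)
    assert abs(b.std() - np.sqrt(v)) < 0.5 * np.sqrt(v)


def test_same_seed_reproduces_draws_exactly():
    data = _mn_data([1] * 5 + [0] * 20)
    cfg = dict(chains=2, iterations=400, warmup=200, seed=42)
    a = sample_posterior(_MN0, data, **cfg)
    b = sample_posterior(_MN0, data, **cfg)
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.log_lik, b.log_lik)
    c = sample_posterior(_MN0, data, chains=2, iterations=400, warmup=200, seed=43)
    assert not np.array_equal(a.draws, c.draws)


def test_loglik_matrix_shape_and_finiteness(small_design):
    from lineagefate.specs import get_spec
    draws = sample_posterior(get_spec("1_4"), small_design,
                             chains=2, iterations=300, warmup=150, seed=3)
    assert draws.log_lik.shape == (2 * 150, small_design.n)
    assert np.isfinite(draws.log_lik).all()
    assert np.isfinite(draws.draws).all()


def test_posterior_under_zero_data_equals_prior():
    # proper priors: with no observations the chain must return the prior
    data = _duration_data(np.array([]))
    draws = sample_posterior(_DUR0, data, chains=4, iterations=4000, warmup=1000, seed=9)
    b = draws.get("b")
    assert abs(np.median(b)) < 1.0  # prior N(0, 10): median 0
    assert abs(np.quantile(b, 0.84) - 10.0) < 2.0  # one prior sd
    sigma = draws.get("sigma")
    half_normal = stats.halfnorm(scale=5.0)
    for q in (0.25, 0.5, 0.75):
        assert abs(np.quantile(sigma, q) - half_normal.ppf(q)) < 1.0


def test_hierarchical_fit_runs_and_recovers_sign(small_design):
    from lineagefate.specs import get_spec
    draws = sample_posterior(get_spec("1_3"), small_design,
                             chains=2, iterations=600, warmup=300, seed=4)
    assert draws.lineage_draws is not None
    assert draws.lineage_draws.shape[2] == small_design.n_lineages
    assert np.median(draws.get("scf")) > 0.5  # strong true SCF effect
    assert np.all(draws.get("lineage_scale") > 0)


# ---- diagnostics ---------------------------------------------------------

def test_summary_quantiles_and_order():
    draws = PosteriorDraws(
        names=["x"], draws=np.array([1.0, 2, 3, 4, 5]).reshape(1, 5, 1),
        log_lik=np.zeros((5, 1)), lineage_draws=None,
        metadata={"rhat": {}, "warnings": []},
    )
    with pytest.warns(UserWarning):
        table = summarize(draws)
    row = table.loc["x"]
    assert row["median"] == 3.0
    assert row["q2.5"] <= row["q25"] <= row["median"] <= row["q75"] <= row["q97.5"]


def test_summary_constant_draws_zero_width():
    draws = PosteriorDraws(
        names=["x"], draws=np.full((2, 10, 1), 7.0), log_lik=np.zeros((20, 1)),
        lineage_draws=None, metadata={"rhat": {}, "warnings": []},
    )
    row = summarize(draws).loc["x"]
    assert row["q2.5"] == row["q97.5"] == 7.0
    assert row["rhat"] == 1.0


def test_rhat_identical_constant_chains_is_one():
    assert rhat(np.full((4, 100), 3.14)) == 1.0


def test_rhat_detects_offset_chain():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 500))
    x[1] += 10
    assert rhat(x) > 1.1


def test_rhat_iid_chains_near_one():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((4, 1000))
    assert 0.99 <= rhat(x) < 1.01


def test_ess_iid_near_nominal_and_correlated_much_smaller():
    rng = np.random.default_rng(2)
    iid = rng.standard_normal((4, 1000))
    assert ess(iid) > 2000
    rho = 0.95
    ar = np.empty((4, 1000))
    ar[:, 0] = rng.standard_normal(4)
    for t in range(1, 1000):
        ar[:, t] = rho * ar[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(4)
    assert ess(ar) < 1000
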