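"""WAIC on the generalization-loss scale: oracles and comparison rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lineagefate.waic import WaicResult, compare_waic, rank_models, waic


def _brute_force_waic(m):
    """Naive double-loop reference implementation."""
    s, n = m.shape
    total = 0.0
    for i in range(n):
        mean_density = sum(np.exp(m[j, i]) for j in range(s)) / s
        lppd_i = np.log(mean_density)
        mean_ll = sum(m[j, i] for j in range(s)) / s
        p_i = sum((m[j, i] - mean_ll) ** 2 for j in range(s)) / (s - 1)
        total += -lppd_i + p_i
    return total / n


def test_zero_variance_draws():
    m = np.tile(np.array([-1.2, -0.7, -2.0]), (5, 1))
    r = waic(m)
    assert r.p_waic_per_sample == 0.0
    assert np.isclose(r.waic_per_sample, -m[0].mean(), rtol=1e-12)


def test_hand_computed_two_draw_example():
    # one observation, two draws with densities 0.5 and 0.25
    m = np.log(np.array([[0.5], [0.25]]))
    r = waic(m)
    # exact closed forms: lppd = log 0.375, p = (log 2)^2 / 2 with the
    # (n-1)-denominator variance
    assert np.isclose(r.lppd_per_sample, np.log(0.375), rtol=1e-14)
    assert np.isclose(r.p_waic_per_sample, np.log(2.0) ** 2 / 2.0, rtol=1e-14)
    assert np.isclose(r.waic_per_sample, -np.log(0.375) + np.log(2.0) ** 2 / 2.0, rtol=1e-14)
    assert np.isclose(r.lppd_per_sample, -0.98083, atol=5e-5)
    assert np.isclose(r.p_waic_per_sample, 0.24026, atol=5e-5)
    assert np.isclose(r.waic_per_sample, 1.22109, atol=5e-5)


def test_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(3)
    for _ in range(5):
        m = rng.normal(-1.0, 0.7, size=(10, 7))
        assert abs(waic(m).waic_per_sample - _brute_force_waic(m)) < 1e-12


def test_invariant_to_draw_order():
    rng = np.random.default_rng(4)
    m = rng.normal(-1, 0.5, (40, 9))
    shuffled = m[rng.permutation(40)]
    assert np.isclose(waic(m).waic_per_sample, waic(shuffled).waic_per_sample, rtol=1e-14)
    assert np.allclose(waic(m).pointwise, waic(shuffled).pointwise)


def test_cross_checks_against_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(5)
    m = rng.normal(-1, 0.5, (2, 100, 11))  # chains x draws x obs
    s = 200
    mine = waic(m.reshape(s, 11))
    idata = az.from_dict(log_likelihood={"y": m})
    theirs = az.waic(idata, scale="log", pointwise=True)
    # arviz penalizes with the population (ddof=0) variance; this package
    # uses the (n-1) estimator, a factor s/(s-1) on the penalty
    p_theirs = theirs.p_waic / 11 * s / (s - 1)
    lppd_theirs = (theirs.elpd_waic + theirs.p_waic) / 11
    assert np.isclose(lppd_theirs, mine.lppd_per_sample, rtol=1e-10)
    assert np.isclose(p_theirs, mine.p_waic_per_sample, rtol=1e-10)
    assert np.isclose(-lppd_theirs + p_theirs, mine.waic_per_sample, rtol=1e-10)


def test_input_validation():
    with pytest.raises(ValueError):
        waic(np.array([[-1.0, -2.0]]))  # single draw
    with pytest.raises(ValueError):
        waic(np.array([[-1.0], [np.inf]]))


def _result(name, w, n=100):
    return WaicResult(model_name=name, n=n, lppd_per_sample=-w,
                      p_waic_per_sample=0.0, waic_per_sample=w,
                      pointwise=np.full(n, w))


def test_compare_reproduces_published_aic_conversion():
    a = _result("m1_4", 0.10000000, n=4424)
    b = _result("m1_2", 0.10045269, n=4424)
    out = compare_waic(a, b)
    assert abs(out["delta_aic_scale"] - 4.00540112) < 1e-8
    assert out["significant"]


@pytest.mark.parametrize("delta,n,expected_sig", [(0.0, 100, False), (1e-4, 1000, False),
                                                  (6e-4, 1000, True)])
def test_significance_threshold(delta, n, expected_sig):
    out = compare_waic(_result("a", 0.5, n), _result("b", 0.5 + delta, n))
    assert np.isclose(out["delta_aic_scale"], abs(delta) * n * 2)
    assert out["significant"] is expected_sig


def test_compare_rejects_mismatched_n():
    with pytest.raises(ValueError):
        compare_waic(_result("a", 0.5, 100), _result("b", 0.5, 101))


def test_rank_orders_and_breaks_ties_by_name():
    table = rank_models([_result("b_model", 0.12), _result("a_model", 0.10),
                         _result("c_model", 0.12)])
    assert list(table["model"]) == ["a_model", "b_model", "c_model"]
    assert table["delta_aic_scale_vs_best"].iloc[0] == 0.0
    assert np.isclose(table["delta_aic_scale_vs_best"].iloc[1], 0.02 * 100 * 2)
    with pytest.raises(ValueError):
        rank_models([])


def test_penalty_approaches_parameter_count_for_regular_model():
    # iid normal data, conjugate posterior for the mean: p_waic * n -> 1
    rng = np.random.default_rng(6)
    n, s = 2000, 4000
    y = rng.standard_normal(n)
    post_mean, post_sd = y.mean(), 1 / np.sqrt(n)
    mu_draws = rng.normal(post_mean, post_sd, s)
    m = -0.5 * np.log(2 * np.pi) - 0.5 * (y[None, :] - mu_draws[:, None]) ** 2
    p_total = waic(m).p_waic_per_sample * n
    assert 0.5 < p_total < 2.0


@given(st.integers(0, 2**31 - 1), st.integers(2, 5))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_chain_concatenation_order_is_irrelevant(seed, n_chains):
    rng = np.random.default_rng(seed)
    per_chain = 30
    m = rng.normal(-1, 0.5, (n_chains * per_chain, 6))
    blocks = [m[i * per_chain:(i + 1) * per_chain] for i in range(n_chains)]
    reordered = np.concatenate(blocks[::-1])
    assert np.isclose(waic(m).waic_per_sample, waic(reordered).waic_per_sample,
                      rtol=1e-13)
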