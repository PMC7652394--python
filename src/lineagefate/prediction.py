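"""Posterior-predictive quantities.

Everything here is sample-based: per-draw MN probabilities, fold changes
of averaged probabilities, predictive interphase-duration samples drawn by
pushing posterior draws through the model's likelihood, quartile/IQR
summaries, and two-sample Kolmogorov-Smirnov distances between predictive
distributions.  Density curves are kernel-smoothed for display only;
statistics always come from the samples.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .sampler import PosteriorDraws
from .specs import ModelSpec
from .simulate import inv_logit

__all__ = [
    "posterior_linear_predictor",
    "predict_mn_prob",
    "mn_fold_change",
    "predictive_duration_samples",
    "duration_quartiles_iqr",
    "ks_distance",
]


def _named_column(draws: PosteriorDraws, name: str) -> np.ndarray:
    if name not in draws.names:
        raise KeyError(f"parameter {name!r} not in posterior ({draws.names})")
    return draws.get(name)


def posterior_linear_predictor(
    draws: PosteriorDraws,
    spec: ModelSpec,
    covariates: dict[str, float],
    mn_status: int | None = None,
    rng: np.random.Generator | None = None,
    integrate_lineage: bool = True,
) -> np.ndarray:
    """Per-draw linear predictor for one covariate setting.

    For hierarchical specs the lineage intercept of a *new* lineage is
    integrated over by drawing one effect per posterior draw from its
    population distribution (normal or Student-t with the drawn scale).
    """
    unknown = set(covariates) - set(spec.terms) - {"micro"}
    if unknown:
        raise KeyError(f"covariate(s) {sorted(unknown)} not in model {spec.name}")
    eta = _named_column(draws, "b").copy()
    for term in spec.terms:
        if term == "micro":
            continue
        x = float(covariates.get(term, 0.0))
        if x != 0.0:
            eta += x * _named_column(draws, term)
    if "micro" in spec.terms:
        if mn_status is None:
            raise ValueError("duration model prediction needs mn_status (0 or 1)")
        if mn_status:
            eta += _named_column(draws, "micro")
    if spec.hierarchical and integrate_lineage:
        rng = rng or np.random.default_rng()
        tau = _named_column(draws, "lineage_scale")
        if spec.lineage_effect == "normal":
            eta = eta + tau * rng.standard_normal(len(eta))
        else:
            eta = eta + tau * rng.standard_t(spec.student_t_df, len(eta))
    return eta


def predict_mn_prob(
    draws: PosteriorDraws,
    spec: ModelSpec,
    covariates: dict[str, float],
    seed: int | None = None,
) -> dict:
    """Posterior distribution of the per-cycle MN probability ``q`` at one
    covariate setting, plus its posterior average."""
    if spec.response != "MN":
        raise ValueError(f"{spec.name} is not an MN-response model")
    rng = np.random.default_rng(seed)
    q = inv_logit(posterior_linear_predictor(draws, spec, covariates, rng=rng))
    return {"samples": q, "average": float(q.mean()), "median": float(np.median(q))}


def mn_fold_change(
    draws: PosteriorDraws,
    spec: ModelSpec,
    covariates_with: dict[str, float],
    covariates_without: dict[str, float],
    seed: int | None = None,
) -> dict:
    """Fold change of the *averaged* posterior MN probabilities between two
    covariate settings (the headline effect size), plus the per-draw ratio
    distribution for uncertainty display."""
    with_ = predict_mn_prob(draws, spec, covariates_with, seed=seed)
    without = predict_mn_prob(draws, spec, covariates_without, seed=None if seed is None else seed + 1)
    if without["average"] == 0:
        raise ZeroDivisionError("denominator probability is zero")
    per_draw = with_["samples"] / np.maximum(without["samples"], 1e-300)
    return {
        "fold_change": with_["average"] / without["average"],
        "average_with": with_["average"],
        "average_without": without["average"],
        "per_draw_ratio": per_draw,
        "ratio_median": float(np.median(per_draw)),
    }


def predictive_duration_samples(
    draws: PosteriorDraws,
    spec: ModelSpec,
    covariates: dict[str, float],
    mn_status: int,
    condition_index: int = 0,
    m: int = 10_000,
    seed: int | None = None,
    integrate_posterior: bool = True,
) -> np.ndarray:
    """``m`` draws from the posterior-predictive interphase-duration
    distribution at one condition.

    Each sample picks one posterior draw (all of them when
    ``integrate_posterior``, otherwise the posterior-median point estimate),
    forms ``mu``, and samples the spec's likelihood with the condition
    group's scale.  ``condition_index`` selects the scale group when scales
    are condition-specific.
    """
    if spec.response != "interphase_duration":
        raise ValueError(f"{spec.name} is not a duration model")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    eta = posterior_linear_predictor(draws, spec, covariates, mn_status=mn_status, rng=rng)
    if spec.sigma_grouping == "by_condition":
        scale_name = f"sigma[{condition_index}]"
        if scale_name not in draws.names:
            raise KeyError(f"unknown condition group {condition_index}")
        scale = _named_column(draws, scale_name)
    elif spec.sigma_grouping == "shared":
        scale = _named_column(draws, "sigma")
    else:
        scale = None

    if integrate_posterior:
        idx = rng.integers(0, len(eta), m)
    else:
        idx = None
        eta = np.full(m, float(np.median(eta)))
        scale = None if scale is None else np.full(m, float(np.median(scale)))
    mu = eta[idx] if idx is not None else eta
    s = scale[idx] if (scale is not None and idx is not None) else scale
    if spec.likelihood == "lognormal":
        return np.exp(rng.normal(mu, s))
    if spec.likelihood == "exponential":
        return rng.exponential(np.exp(mu))
    if spec.likelihood == "gamma":
        return rng.gamma(shape=s, scale=np.exp(mu) / s)
    raise ValueError(f"no predictive sampler for likelihood {spec.likelihood}")


def duration_quartiles_iqr(samples: np.ndarray) -> dict:
    """Empirical quartiles (linear interpolation) and IQR = q75 - q25."""
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {"q25": float(q25), "q50": float(q50), "q75": float(q75), "iqr": float(q75 - q25)}


def ks_distance(samples_a: np.ndarray, samples_b: np.ndarray) -> dict:
    """Two-sample Kolmogorov-Smirnov sup-distance and asymptotic p-value.

    Applied to large predictive samples the p-value is display-only (any
    visible difference is 'significant' at m = 10,000 per side).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return {"D": float(res.statistic), "p_value": float(res.pvalue)}
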