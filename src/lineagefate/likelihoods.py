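"""Pointwise log-likelihoods for every model spec.

All likelihoods share the linear predictor

    mu_n = b + sum_term coef_term * X_term,n  (+ lin_{l(n)} if hierarchical)

For the MN response, ``q_n = inv_logit(mu_n)`` is the per-cycle MN
probability.  For durations, ``exp(mu_n)`` is the log-normal median; the
exponential and gamma alternatives are parameterized so that ``exp(mu_n)``
is the *mean* (gamma shape ``alpha_c`` per scale group, rate
``alpha_c / exp(mu_n)``; with ``alpha_c = 1`` the gamma reduces exactly to
the exponential).

Duration likelihood vectors cover only the records with an observed
interphase duration (cycles censored before nuclear-envelope breakdown
contribute nothing); MN vectors cover every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .design import ModelData
from .specs import ModelSpec

__all__ = ["ParameterSet", "pointwise_loglik", "linear_predictor", "response_length"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ParameterSet:
    """A single point in parameter space for one :class:`ModelSpec`.

    ``sigma`` holds the scale parameters on their natural scale: log-normal
    sd or gamma shape, one per scale group (1 if shared, ``n_conditions``
    if by-condition).  ``lineage_effects`` has one entry per lineage when
    the spec is hierarchical.
    """

    b: float
    coef: dict[str, float] = field(default_factory=dict)
    sigma: np.ndarray | None = None
    lineage_effects: np.ndarray | None = None
    lineage_scale: float | None = None


def response_length(spec: ModelSpec, data: ModelData) -> int:
    """Number of observations the spec's likelihood is evaluated on."""
    if spec.response == "MN":
        return data.n
    return int(data.duration_mask.sum())


def linear_predictor(spec: ModelSpec, params: ParameterSet, data: ModelData) -> np.ndarray:
    """mu_n over all n records (before any duration masking)."""
    mu = np.full(data.n, params.b, dtype=float)
    for term in spec.terms:
        c = params.coef.get(term, 0.0)
        if c != 0.0:
            mu += c * data.term_column(term)
    if spec.hierarchical:
        if params.lineage_effects is None:
            raise ValueError("hierarchical spec requires lineage_effects")
        mu += params.lineage_effects[data.lineage_idx]
    return mu


def _sigma_per_obs(spec: ModelSpec, params: ParameterSet, cond_idx: np.ndarray) -> np.ndarray:
    if params.sigma is None:
        raise ValueError(f"{spec.likelihood} likelihood requires a scale parameter")
    sigma = np.asarray(params.sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("scale parameters must be > 0")
    if spec.sigma_grouping == "by_condition":
        return sigma[cond_idx]
    return np.full(len(cond_idx), sigma.reshape(-1)[0])


def pointwise_loglik(spec: ModelSpec, params: ParameterSet, data: ModelData) -> np.ndarray:
    """Vector of per-observation log densities at one parameter point."""
    mu = linear_predictor(spec, params, data)
    if spec.response == "MN":
        y = data.mn
        # stable Bernoulli-logit: log q = -log1p(e^-mu), log(1-q) = -log1p(e^mu)
        return -np.logaddexp(0.0, np.where(y == 1, -mu, mu))

    mask = data.duration_mask
    y = data.duration[mask]
    if np.any(y <= 0):
        raise ValueError("durations must be > 0")
    mu = mu[mask]
    cond = data.condition_idx[mask]
    logy = np.log(y)
    if spec.likelihood == "lognormal":
        s = _sigma_per_obs(spec, params, cond)
        z = (logy - mu) / s
        return -logy - np.log(s) - 0.5 * _LOG_2PI - 0.5 * z * z
    if spec.likelihood == "exponential":
        # rate exp(-mu): mean exp(mu)
        return -mu - y * np.exp(-mu)
    if spec.likelihood == "gamma":
        a = _sigma_per_obs(spec, params, cond)  # shape alpha_c
        log_rate = np.log(a) - mu  # rate = alpha / mean
        return a * log_rate - gammaln(a) + (a - 1.0) * logy - np.exp(log_rate) * y
    raise AssertionError(f"unhandled likelihood {spec.likelihood}")
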