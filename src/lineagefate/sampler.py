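"""Posterior sampling via adaptive random-walk Metropolis-within-Gibbs.

The sampler is a dependency-free reference implementation of the sampling
contract used by the package: any MCMC that yields exchangeable posterior
draws together with the pointwise log-likelihood matrix needed for WAIC
would do.  Scalar parameters (bias, coefficients, log-scales) take
one-at-a-time Gaussian random-walk updates whose step sizes adapt toward a
0.44 acceptance rate during warmup; per-lineage random intercepts are
updated as a vectorized block with independent accept/reject per lineage
(valid because, conditional on the shared parameters, both likelihood and
prior factorize over lineages).

Scale-like parameters (log-normal sigma, gamma shape, hierarchical scale)
are sampled on the log scale with the Jacobian folded into the prior, so
their half-normal priors are honoured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ModelData
from .likelihoods import ParameterSet, pointwise_loglik, response_length
from .specs import ModelSpec

__all__ = ["Priors", "SamplerConfig", "PosteriorDraws", "sample_posterior", "SamplingError"]

_TARGET_ACC = 0.44


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults, recorded with every result."""

    coef_sd: float = 10.0  # Normal(0, coef_sd) on bias and coefficients
    scale_sd: float = 5.0  # half-Normal(0, scale_sd) on sigma / gamma shape
    lineage_scale_sd: float = 5.0  # half-Normal on the hierarchical scale

    def as_dict(self) -> dict:
        return {
            "coef_sd": self.coef_sd,
            "scale_sd": self.scale_sd,
            "lineage_scale_sd": self.lineage_scale_sd,
        }


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    iterations: int = 2000  # total per chain, including warmup
    warmup: int = 1000
    seed: int | None = None
    priors: Priors = field(default_factory=Priors)

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup


@dataclass
class PosteriorDraws:
    """Retained draws plus the pointwise log-likelihood matrix.

    ``draws`` is (chains, kept, n_named) over the named scalar parameters;
    ``lineage_draws`` (chains, kept, n_lineages) exists only for
    hierarchical specs.  ``log_lik`` is (chains*kept, n_observations) in
    chain-major order.
    """

    names: list[str]
    draws: np.ndarray
    log_lik: np.ndarray
    lineage_draws: np.ndarray | None
    metadata: dict

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """All retained draws of one named parameter, flattened."""
        return self.draws[:, :, self.names.index(name)].reshape(-1)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameter_set_at(self, i: int, spec: ModelSpec, data: ModelData) -> ParameterSet:
        """Reconstruct the :class:`ParameterSet` of flattened draw ``i``."""
        c, k = divmod(i, self.draws.shape[1])
        vec = self.draws[c, k]
        named = dict(zip(self.names, vec))
        coef = {t: named[t] for t in spec.terms}
        sigma = None
        if spec.likelihood in ("lognormal", "gamma"):
            if spec.sigma_grouping == "by_condition":
                sigma = np.array([named[f"sigma[{j}]"] for j in range(data.n_conditions)])
            else:
                sigma = np.array([named["sigma"]])
        lin = self.lineage_draws[c, k] if self.lineage_draws is not None else None
        tau = named.get("lineage_scale")
        return ParameterSet(
            b=named["b"], coef=coef, sigma=sigma, lineage_effects=lin, lineage_scale=tau
        )


class _Posterior:
    """Unconstrained-parameter view of (spec, data, priors).

    theta layout: [b, coefs..., log-scales..., log-lineage-scale?];
    lineage effects live in a separate vector updated as a block.
    """

    def __init__(self, spec: ModelSpec, data: ModelData, priors: Priors):
        self.spec = spec
        self.data = data
        self.priors = priors
        self.names: list[str] = ["b"] + list(spec.terms)
        self.n_scales = 0
        if spec.likelihood in ("lognormal", "gamma"):
            self.n_scales = data.n_conditions if spec.sigma_grouping == "by_condition" else 1
            if self.n_scales == 1:
                self.names.append("sigma")
            else:
                self.names += [f"sigma[{j}]" for j in range(self.n_scales)]
        self.scale_slice = slice(1 + len(spec.terms), 1 + len(spec.terms) + self.n_scales)
        self.hierarchical = spec.hierarchical
        if self.hierarchical:
            self.names.append("lineage_scale")
        self.n_theta = 1 + len(spec.terms) + self.n_scales + int(self.hierarchical)
        # per-lineage observation index for block updates
        if spec.response == "MN":
            self._lin_of_obs = data.lineage_idx
        else:
            self._lin_of_obs = data.lineage_idx[data.duration_mask]
        self.n_obs = response_length(spec, data)

    def params_at(self, theta: np.ndarray, lin: np.ndarray | None) -> ParameterSet:
        coef = dict(zip(self.spec.terms, theta[1 : 1 + len(self.spec.terms)]))
        sigma = np.exp(theta[self.scale_slice]) if self.n_scales else None
        tau = math.exp(theta[-1]) if self.hierarchical else None
        return ParameterSet(
            b=theta[0], coef=coef, sigma=sigma, lineage_effects=lin, lineage_scale=tau
        )

    def loglik_vector(self, theta: np.ndarray, lin: np.ndarray | None) -> np.ndarray:
        return pointwise_loglik(self.spec, self.params_at(theta, lin), self.data)

    def log_prior_theta(self, theta: np.ndarray) -> float:
        sd = self.priors.coef_sd
        lp = -0.5 * float(np.sum(theta[: 1 + len(self.spec.terms)] ** 2)) / sd**2
        if self.n_scales:
            s = theta[self.scale_slice]  # log sigma; Jacobian = +s
            sig = np.exp(s)
            lp += float(np.sum(s - 0.5 * sig**2 / self.priors.scale_sd**2))
        if self.hierarchical:
            s = theta[-1]
            tau = math.exp(s)
            lp += s - 0.5 * tau**2 / self.priors.lineage_scale_sd**2
        return lp

    def log_prior_lineage(self, lin: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Per-lineage prior log density of the random intercepts."""
        tau = math.exp(theta[-1])
        if self.spec.lineage_effect == "normal":
            return -np.log(tau) - 0.5 * (lin / tau) ** 2
        v = self.spec.student_t_df
        const = (
            math.lgamma((v + 1) / 2) - math.lgamma(v / 2) - 0.5 * math.log(v * math.pi)
        )
        return const - np.log(tau) - 0.5 * (v + 1) * np.log1p((lin / tau) ** 2 / v)

    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.n_theta)
        d = self.data
        if self.spec.response == "MN":
            p = min(max(d.mn.mean(), 1e-3), 1 - 1e-3)
            theta[0] = math.log(p / (1 - p))
        else:
            logy = np.log(d.duration[d.duration_mask])
            theta[0] = float(logy.mean()) if logy.size else 0.0
            if self.n_scales:
                s = float(logy.std()) if logy.size > 1 else 1.0
                theta[self.scale_slice] = math.log(max(s, 0.05))
        if self.hierarchical:
            theta[-1] = math.log(0.5)
        theta += 0.1 * rng.standard_normal(self.n_theta)
        return theta


def sample_posterior(
    spec: ModelSpec,
    data: ModelData,
    config: SamplerConfig | None = None,
    **overrides,
) -> PosteriorDraws:
    """Draw from the posterior of ``spec`` given ``data``.

    Reproducible for a fixed ``config.seed``; chains run sequentially from
    independently spawned RNG streams.  A convergence warning (split R-hat
    > 1.05 on any named parameter) is attached to the metadata rather than
    raised, so callers can decide how strict to be.
    """
    if config is None:
        config = SamplerConfig(**overrides)
    elif overrides:
        config = SamplerConfig(**{**config.__dict__, **overrides})
    if config.kept <= 0:
        raise SamplingError("iterations must exceed warmup")
    post = _Posterior(spec, data, config.priors)
    # n_obs == 0 is allowed: the chain then samples the (proper) prior,
    # which is how prior/posterior agreement under zero data is checked

    n_lin = data.n_lineages if post.hierarchical else 0
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)

    draws = np.empty((config.chains, config.kept, post.n_theta))
    lineage_draws = np.empty((config.chains, config.kept, n_lin)) if n_lin else None
    log_lik = np.empty((config.chains, config.kept, post.n_obs))

    for c in range(config.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = post.initial_theta(rng)
        lin = 0.01 * rng.standard_normal(n_lin) if n_lin else None
        ll_vec = post.loglik_vector(theta, lin)
        ll_sum = float(ll_vec.sum())
        lp_theta = post.log_prior_theta(theta)

        step = np.full(post.n_theta, 0.1)
        lin_step = np.full(n_lin, 0.5) if n_lin else None

        for it in range(config.iterations):
            adapt = it < config.warmup
            gamma = (it + 1) ** -0.6 if adapt else 0.0
            for j in range(post.n_theta):
                prop = theta.copy()
                prop[j] += step[j] * rng.standard_normal()
                try:
                    ll_prop = post.loglik_vector(prop, lin)
                except (ValueError, FloatingPointError):
                    ll_prop = None
                if ll_prop is None or not np.isfinite(ll_prop).all():
                    accept = False
                else:
                    lp_prop = post.log_prior_theta(prop)
                    delta = float(ll_prop.sum()) + lp_prop - ll_sum - lp_theta
                    if post.hierarchical and j == post.n_theta - 1:
                        delta += float(
                            np.sum(post.log_prior_lineage(lin, prop))
                            - np.sum(post.log_prior_lineage(lin, theta))
                        )
                    accept = math.log(rng.random()) < delta
                if accept:
                    theta, ll_vec, ll_sum, lp_theta = prop, ll_prop, float(ll_prop.sum()), lp_prop
                if adapt:
                    step[j] *= math.exp(gamma * ((1.0 if accept else 0.0) - _TARGET_ACC))

            if n_lin:
                prop_lin = lin + lin_step * rng.standard_normal(n_lin)
                ll_prop = post.loglik_vector(theta, prop_lin)
                d_lik = np.bincount(
                    post._lin_of_obs, weights=ll_prop - ll_vec, minlength=n_lin
                )
                d_pri = post.log_prior_lineage(prop_lin, theta) - post.log_prior_lineage(lin, theta)
                acc = np.log(rng.random(n_lin)) < d_lik + d_pri
                if acc.any():
                    lin = np.where(acc, prop_lin, lin)
                    ll_vec = post.loglik_vector(theta, lin)
                    ll_sum = float(ll_vec.sum())
                if adapt:
                    lin_step *= np.exp(gamma * (acc.astype(float) - _TARGET_ACC))

            if it >= config.warmup:
                k = it - config.warmup
                out = theta.copy()
                if post.n_scales:
                    out[post.scale_slice] = np.exp(out[post.scale_slice])
                if post.hierarchical:
                    out[-1] = math.exp(out[-1])
                draws[c, k] = out
                if n_lin:
                    lineage_draws[c, k] = lin
                log_lik[c, k] = ll_vec

    if not np.isfinite(draws).all():
        raise SamplingError("non-finite draws after warmup")

    from .diagnostics import rhat as _rhat  # local import to avoid a cycle

    rhats = {name: float(_rhat(draws[:, :, j])) for j, name in enumerate(post.names)}
    warnings = [
        f"R-hat {v:.3f} > 1.05 for {k}" for k, v in rhats.items() if v > 1.05
    ]
    return PosteriorDraws(
        names=post.names,
        draws=draws,
        log_lik=log_lik.reshape(config.chains * config.kept, post.n_obs),
        lineage_draws=lineage_draws,
        metadata={
            "spec": spec.name,
            "seed": config.seed,
            "chains": config.chains,
            "iterations": config.iterations,
            "warmup": config.warmup,
            "priors": config.priors.as_dict(),
            "rhat": rhats,
            "warnings": warnings,
            "n_obs": post.n_obs,
        },
    )
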