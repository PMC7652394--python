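"""WAIC on the generalization-loss scale and the AIC-scale comparison rule.

WAIC here is reported in **nat/sample** (generalization-loss scale):

    lppd_i = log mean_s exp(loglik_si)          (log-sum-exp stabilized)
    p_i    = Var_s loglik_si                     (sample variance, n-1)
    waic   = sum_i (-lppd_i + p_i) / n

The conventional deviance-scale value, ``2 * n * waic_per_sample``, is
also carried for cross-checking against other toolchains.  Two models'
predictive performances are declared significantly different when the
per-sample WAIC gap, converted back to the AIC scale
(``|delta| * n * 2``), exceeds one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["WaicResult", "waic", "compare_waic", "rank_models"]


@dataclass(frozen=True)
class WaicResult:
    model_name: str
    n: int
    lppd_per_sample: float
    p_waic_per_sample: float
    waic_per_sample: float
    pointwise: np.ndarray  # per-observation -lppd_i + p_i

    @property
    def deviance_scale(self) -> float:
        return 2.0 * self.n * self.waic_per_sample


def waic(log_lik: np.ndarray, model_name: str = "") -> WaicResult:
    """WAIC from an (S draws x n observations) pointwise log-likelihood
    matrix.  Draw order and chain concatenation order are irrelevant."""
    m = np.asarray(log_lik, dtype=float)
    if m.ndim != 2:
        raise ValueError("log_lik must be 2-D (draws x observations)")
    s, n = m.shape
    if s < 2:
        raise ValueError("need at least 2 draws for the variance penalty")
    if not np.isfinite(m).all():
        raise ValueError("non-finite entries in log_lik")
    lppd_i = logsumexp(m, axis=0) - np.log(s)
    p_i = m.var(axis=0, ddof=1)
    pointwise = -lppd_i + p_i
    return WaicResult(
        model_name=model_name,
        n=n,
        lppd_per_sample=float(lppd_i.sum() / n),
        p_waic_per_sample=float(p_i.sum() / n),
        waic_per_sample=float(pointwise.sum() / n),
        pointwise=pointwise,
    )


def compare_waic(a: WaicResult, b: WaicResult, n: int | None = None) -> dict:
    """Per-sample WAIC difference (b - a) and its AIC-scale magnitude.

    A gap greater than one on the AIC scale (``|delta| * n * 2``) is
    considered significant.
    """
    if n is None:
        n = a.n
    if a.n != b.n or a.n != n:
        raise ValueError(f"models computed on different n: {a.n} vs {b.n} vs {n}")
    delta = b.waic_per_sample - a.waic_per_sample
    aic_scale = abs(delta) * n * 2.0
    return {
        "delta_per_sample": delta,
        "delta_aic_scale": aic_scale,
        "significant": aic_scale > 1.0,
    }


def rank_models(results: list[WaicResult]) -> pd.DataFrame:
    """Rank ascending by per-sample WAIC (smaller predicts better); ties
    broken by model name.  Gaps to the best are given on the AIC scale."""
    if not results:
        raise ValueError("no WAIC results to rank")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"results computed on different n: {sorted(ns)}")
    ordered = sorted(results, key=lambda r: (r.waic_per_sample, r.model_name))
    best = ordered[0].waic_per_sample
    rows = [
        {
            "model": r.model_name,
            "n": r.n,
            "lppd_per_sample": r.lppd_per_sample,
            "p_waic_per_sample": r.p_waic_per_sample,
            "waic_per_sample": r.waic_per_sample,
            "waic_deviance_scale": r.deviance_scale,
            "delta_aic_scale_vs_best": (r.waic_per_sample - best) * r.n * 2.0,
        }
        for r in ordered
    ]
    return pd.DataFrame(rows)
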