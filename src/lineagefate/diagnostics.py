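"""Convergence diagnostics and posterior summaries.

R-hat is the rank-normalized split statistic: draws are split-halved by
chain, rank-normalized across everything, and the classic potential scale
reduction factor is computed on the normal scores.  ESS uses Geyer's
initial-monotone-sequence truncation of the autocorrelation sum on the
split chains.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .sampler import PosteriorDraws

__all__ = ["rhat", "ess", "summarize"]


def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, n) -> (2*chains, n//2), dropping an odd trailing draw."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    flat = x.reshape(-1)
    # average ties so identical values get identical scores
    ranks = pd.Series(flat).rank(method="average").to_numpy()
    z = ndtri((ranks - 3.0 / 8.0) / (flat.size + 1.0 / 4.0))
    return z.reshape(x.shape)


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat for one parameter.

    ``chains`` is (n_chains, n_draws); a single chain is split in half
    (with a warning).  Chains that are all identical constants report 1.0
    by convention (the 0/0 case of a degenerate posterior).
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    if x.shape[0] == 1:
        _warnings.warn("single chain: R-hat computed on split halves", stacklevel=2)
    if np.ptp(x) == 0:
        return 1.0
    z = _rank_normalize(_split_chains(x))
    m, n = z.shape
    if n < 2:
        return float("nan")
    means = z.mean(axis=1)
    w = float(z.var(axis=1, ddof=1).mean())
    b = n * float(means.var(ddof=1))
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone sequence."""
    x = _split_chains(np.atleast_2d(np.asarray(chains, dtype=float)))
    m, n = x.shape
    if np.ptp(x) == 0:
        return float(m * n)
    x = x - x.mean(axis=1, keepdims=True)
    # per-chain autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    var = acov[:, 0].mean()
    if var == 0:
        return float(m * n)
    rho = acov.mean(axis=0) / var
    # Geyer: sum lag pairs (rho_2k + rho_2k+1) while positive, forced
    # non-increasing; tau = 2 * sum(pairs) - 1
    pair_sums = []
    for t in range(0, n - 1, 2):
        p = rho[t] + rho[t + 1]
        if p <= 0:
            break
        pair_sums.append(p)
    if pair_sums:
        tau = 2.0 * float(np.sum(np.minimum.accumulate(pair_sums))) - 1.0
    else:
        tau = 1.0
    return float(m * n / max(tau, 1.0 / (m * n)))


def summarize(draws: PosteriorDraws, include_lineage: bool = False) -> pd.DataFrame:
    """Quantile summary table: median, 50% and 95% credible intervals,
    split R-hat and ESS per parameter.  Quantiles use linear interpolation.
    """
    if draws.n_draws < 4:
        raise ValueError("need at least 4 retained draws to summarize")
    rows = []
    for j, name in enumerate(draws.names):
        x = draws.draws[:, :, j]
        flat = x.reshape(-1)
        q = np.percentile(flat, [2.5, 25, 50, 75, 97.5])
        rows.append(
            {
                "parameter": name,
                "median": q[2],
                "q2.5": q[0],
                "q25": q[1],
                "q75": q[3],
                "q97.5": q[4],
                "rhat": rhat(x),
                "ess": ess(x),
            }
        )
    if include_lineage and draws.lineage_draws is not None:
        for i in range(draws.lineage_draws.shape[2]):
            x = draws.lineage_draws[:, :, i]
            flat = x.reshape(-1)
            q = np.percentile(flat, [2.5, 25, 50, 75, 97.5])
            rows.append(
                {
                    "parameter": f"lin[{i}]",
                    "median": q[2],
                    "q2.5": q[0],
                    "q25": q[1],
                    "q75": q[3],
                    "q97.5": q[4],
                    "rhat": rhat(x),
                    "ess": ess(x),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")
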