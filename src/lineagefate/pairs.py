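"""Matched sister-lineage comparison.

For every division whose two daughter subtrees *differ* in micronucleus
status (exactly one side contains at least one MN-positive cell), the two
subtrees form a matched pair: same mother, same condition, same time —
differing in whether MN formed.  Each side's subsequent abnormalities
(MN count, regression, fusion, death, mitotic delay, and number of
mitoses) are tallied and the sides compared; the resulting 2x2 table
(MN+ side more abnormal / not, MN- side more abnormal / not) is tested
with Pearson's chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import MITOTIC_DELAY_HOURS, LineageTree

__all__ = [
    "SisterPair",
    "find_matched_pairs",
    "compare_pairs",
    "chisq_2x2",
    "event_probability",
    "pair_table",
]

_EVENT_KEYS = ("mn", "regression", "fusion", "death", "mitotic_delay")


@dataclass(frozen=True)
class AbnormalityTally:
    mn: int
    regression: int
    fusion: int
    death: int
    mitotic_delay: int
    mitoses: int

    @property
    def events(self) -> int:
        return sum(getattr(self, k) for k in _EVENT_KEYS)


@dataclass(frozen=True)
class SisterPair:
    lineage_id: str
    division_cell_id: str
    mn_positive_id: str
    mn_negative_id: str
    positive: AbnormalityTally
    negative: AbnormalityTally

    @property
    def verdict(self) -> str:
        """Which side accumulated strictly more abnormalities.

        A side scores one point per excess event and one point for having
        *fewer* mitoses than its sister (failure to keep cycling is itself
        an abnormality).  Equal scores are a tie.
        """
        pos = self.positive.events + int(self.positive.mitoses < self.negative.mitoses)
        neg = self.negative.events + int(self.negative.mitoses < self.positive.mitoses)
        if pos > neg:
            return "MN_plus_more"
        if neg > pos:
            return "MN_minus_more"
        return "tie"


def _tally(tree: LineageTree, root_id: str, discount_index_mn: bool = False) -> AbnormalityTally:
    recs = tree.subtree_records(root_id)
    mn = sum(r.micronuclei for r in recs)
    if discount_index_mn and mn > 0:
        # the micronucleus that defines the MN+ side is the matching
        # criterion, not a subsequent abnormality; only *additional* MN
        # count toward the side's tally
        mn -= 1
    return AbnormalityTally(
        mn=mn,
        regression=sum(r.regression for r in recs),
        fusion=sum(r.fused_with is not None for r in recs),
        death=sum(r.death for r in recs),
        mitotic_delay=sum(
            r.mitotic_duration is not None and r.mitotic_duration > MITOTIC_DELAY_HOURS
            for r in recs
        ),
        mitoses=sum(r.t_division is not None for r in recs),
    )


def _subtree_has_mn(tree: LineageTree, root_id: str) -> bool:
    return any(r.micronuclei for r in tree.subtree_records(root_id))


def find_matched_pairs(trees: list[LineageTree]) -> list[SisterPair]:
    """All sister pairs discordant for MN across a set of trees.

    Bipolar divisions only (tripolar mitoses have no unique sister);
    divisions where both or neither daughter subtree shows MN are skipped.
    """
    pairs: list[SisterPair] = []
    for tree in trees:
        for cell_id in sorted(tree.cells):
            kids = tree.children.get(cell_id, [])
            if len(kids) != 2:
                continue
            a, b = kids
            mn_a, mn_b = _subtree_has_mn(tree, a), _subtree_has_mn(tree, b)
            if mn_a == mn_b:
                continue
            pos, neg = (a, b) if mn_a else (b, a)
            pairs.append(
                SisterPair(
                    lineage_id=tree.lineage_id,
                    division_cell_id=cell_id,
                    mn_positive_id=pos,
                    mn_negative_id=neg,
                    positive=_tally(tree, pos, discount_index_mn=True),
                    negative=_tally(tree, neg),
                )
            )
    return pairs


def compare_pairs(pairs: list[SisterPair]) -> dict:
    """Aggregate pair verdicts into the 2x2 contingency table.

    Rows: MN+ side / MN- side; columns: (more abnormal than sister, not).
    Ties count as "not more abnormal" on both rows.
    """
    if not pairs:
        raise ValueError("no pairs to compare")
    n = len(pairs)
    plus_more = sum(p.verdict == "MN_plus_more" for p in pairs)
    minus_more = sum(p.verdict == "MN_minus_more" for p in pairs)
    table = np.array([[plus_more, n - plus_more], [minus_more, n - minus_more]])
    return {
        "n_pairs": n,
        "mn_plus_more": plus_more,
        "mn_minus_more": minus_more,
        "ties": n - plus_more - minus_more,
        "table": table,
        "verdicts": [p.verdict for p in pairs],
    }


def chisq_2x2(table: np.ndarray, correction: bool = False) -> dict:
    """Pearson chi-square for a 2x2 table, df = 1.

    Closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); Yates continuity
    correction off by default.  Requires positive margins.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square undefined")
    n = t.sum()
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    statistic = n * num**2 / np.prod(margins)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return {"statistic": float(statistic), "df": 1, "p_value": p_value}


def event_probability(k: int, n: int, method: str = "all") -> dict | float:
    """Estimate of the abnormality probability from k events in n pairs.

    ``mle`` k/n; ``jeffreys_mean`` (k+1/2)/(n+1); ``laplace_mean``
    (k+1)/(n+2); ``beta_median`` median of Beta(k+1/2, n-k+1/2).
    ``all`` returns every estimator keyed by name.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    est = {
        "mle": k / n,
        "jeffreys_mean": (k + 0.5) / (n + 1),
        "laplace_mean": (k + 1) / (n + 2),
        "beta_median": float(stats.beta.median(k + 0.5, n - k + 0.5)),
    }
    if method == "all":
        return est
    if method not in est:
        raise ValueError(f"unknown method {method!r}")
    return est[method]


def pair_table(pairs: list[SisterPair]) -> pd.DataFrame:
    """Per-pair tally table (TSV-friendly)."""
    rows = []
    for p in pairs:
        row = {
            "lineage_id": p.lineage_id,
            "division": p.division_cell_id,
            "mn_positive": p.mn_positive_id,
            "mn_negative": p.mn_negative_id,
            "verdict": p.verdict,
        }
        for side, tally in (("pos", p.positive), ("neg", p.negative)):
            for k in _EVENT_KEYS + ("mitoses",):
                row[f"{side}_{k}"] = getattr(tally, k)
        rows.append(row)
    return pd.DataFrame(rows)
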