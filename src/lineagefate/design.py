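"""Covariate coding for the regression models.

Each observed cell cycle is coded with dummy variables derived from its
experimental condition:

* ``SCF``  — 1 iff (SIS2-3, sgF11): the cell carries a single induced
  sister-chromatid fusion;
* ``RNF``  — 1 iff (CTRL48, sgF11): the cassette was cut and repaired
  without a fusion;
* ``SIS``  — 1 iff cell line SIS2-3 (cell-line effect vs CTRL48);
* ``STG``  — 1 iff stage N+x (founder already fluorescent at movie start);
* ``MN``   — the per-cycle micronucleus flag (response of the MN model,
  covariate of the duration model).

Baseline (all dummies 0) is a CTRL48 mock-treated 1+x cell without MN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TidyDataset

__all__ = ["ModelData", "design_matrix", "condition_covariates", "ConsistencyError"]

#: Order of columns in :attr:`ModelData.X`.
TERMS = ("scf", "rnf", "stg", "sis2-3")


class ConsistencyError(ValueError):
    """A record's flags contradict its condition labels."""


@dataclass
class ModelData:
    """Numeric arrays the samplers consume.

    ``X`` holds the condition dummies (columns in :data:`TERMS` order),
    ``mn`` the micronucleus indicator, ``duration`` the interphase duration
    in hours with NaN where unobserved and ``duration_mask`` marking the
    observed entries.  ``lineage_idx`` / ``condition_idx`` are contiguous
    0-based codes assigned lexicographically.
    """

    X: np.ndarray  # (n, 4) float
    mn: np.ndarray  # (n,) int
    duration: np.ndarray  # (n,) float, NaN when unobserved
    duration_mask: np.ndarray  # (n,) bool
    lineage_idx: np.ndarray  # (n,) int
    condition_idx: np.ndarray  # (n,) int
    lineage_ids: list[str]
    conditions: list[tuple[str, str, str]]

    @property
    def n(self) -> int:
        return len(self.mn)

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def term_column(self, term: str) -> np.ndarray:
        if term == "micro":
            return self.mn.astype(float)
        return self.X[:, TERMS.index(term)]


def condition_covariates(cell_line: str, treatment: str, stage: str) -> dict[str, float]:
    """Dummy coding of one experimental condition as a covariate dict."""
    sis = cell_line == "SIS2-3"
    cut = treatment == "sgF11"
    return {
        "scf": float(sis and cut),
        "rnf": float((not sis) and cut),
        "stg": float(stage == "N+x"),
        "sis2-3": float(sis),
    }


def design_matrix(dataset: TidyDataset) -> ModelData:
    """Code a tidy dataset into :class:`ModelData`.

    Raises :class:`ConsistencyError` for a mock-treated record flagged as
    fading (the reporter cannot fade where it was never rearranged).
    """
    recs = dataset.records
    n = len(recs)
    for r in recs:
        if r.treatment == "mCit" and r.fading:
            raise ConsistencyError(
                f"lineage {r.lineage_id} cell {r.cell_id}: fading under mock treatment"
            )

    lineage_ids = sorted({r.lineage_id for r in recs})
    lin_code = {lid: i for i, lid in enumerate(lineage_ids)}
    conditions = sorted({r.condition for r in recs})
    cond_code = {c: i for i, c in enumerate(conditions)}

    X = np.zeros((n, 4))
    mn = np.zeros(n, dtype=int)
    duration = np.full(n, np.nan)
    lineage_idx = np.zeros(n, dtype=int)
    condition_idx = np.zeros(n, dtype=int)
    for i, r in enumerate(recs):
        sis = r.cell_line == "SIS2-3"
        cut = r.treatment == "sgF11"
        X[i, 0] = float(sis and cut)  # scf
        X[i, 1] = float((not sis) and cut)  # rnf
        X[i, 2] = float(r.stage == "N+x")  # stg
        X[i, 3] = float(sis)  # sis2-3
        mn[i] = int(r.micronuclei)
        if r.interphase_duration is not None:
            # present iff NEBD was observed; cycles censored before NEBD
            # carry no duration and contribute only to the MN model
            duration[i] = r.interphase_duration
        lineage_idx[i] = lin_code[r.lineage_id]
        condition_idx[i] = cond_code[r.condition]
    return ModelData(
        X=X,
        mn=mn,
        duration=duration,
        duration_mask=~np.isnan(duration),
        lineage_idx=lineage_idx,
        condition_idx=condition_idx,
        lineage_ids=lineage_ids,
        conditions=conditions,
    )
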