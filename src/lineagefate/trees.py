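"""Lineage trees and lineage-level abnormality features.

A lineage tree is the rooted tree of all observed cell cycles descending
from one mCitrine-positive founder; divisions are bifurcations (tri-
furcations after tripolar mitosis) and sister-cell fusions are extra
links between coexisting branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import CellRecord, TidyDataset

__all__ = [
    "LineageTree",
    "TopologyError",
    "build_trees",
    "lineage_features",
    "abnormality_percentages",
    "FEATURES",
]

#: Lineage-level abnormality flags, in reporting order.
FEATURES = (
    "no_mitosis",
    "mitotic_delay",
    "MN",
    "bi_multi",
    "death",
    "fading",
    "tripolar",
    "regression",
    "cell_fusion",
)

#: A single mitosis longer than this (hours, strict) flags the lineage as
#: mitotically delayed.
MITOTIC_DELAY_HOURS = 2.0


class TopologyError(ValueError):
    """The records of a lineage do not form a valid tree."""


@dataclass
class LineageTree:
    lineage_id: str
    condition: tuple[str, str, str]
    root: CellRecord
    cells: dict[str, CellRecord]
    children: dict[str, list[str]] = field(default_factory=dict)
    fusion_links: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def subtree_ids(self, cell_id: str) -> list[str]:
        """All cell ids in the subtree rooted at ``cell_id`` (inclusive),
        preorder."""
        out: list[str] = []
        stack = [cell_id]
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(reversed(self.children.get(cid, [])))
        return out

    def subtree_records(self, cell_id: str) -> list[CellRecord]:
        return [self.cells[c] for c in self.subtree_ids(cell_id)]

    @property
    def n_divisions(self) -> int:
        return sum(1 for cid in self.cells if self.children.get(cid))


def build_trees(dataset: TidyDataset) -> list[LineageTree]:
    """Group records by lineage and assemble one tree per lineage.

    Children are ordered by daughter label; fusion links are resolved
    bidirectionally and stored once per pair.
    """
    by_lin: dict[str, list[CellRecord]] = {}
    for r in dataset.records:
        by_lin.setdefault(r.lineage_id, []).append(r)

    trees: list[LineageTree] = []
    for lineage_id, recs in by_lin.items():
        cells = {r.cell_id: r for r in recs}
        roots = [r for r in recs if r.parent_id is None]
        if len(roots) != 1:
            raise TopologyError(f"lineage {lineage_id}: {len(roots)} roots")
        children: dict[str, list[str]] = {cid: [] for cid in cells}
        for r in recs:
            if r.parent_id is None:
                continue
            if r.parent_id not in cells:
                raise TopologyError(
                    f"lineage {lineage_id}: cell {r.cell_id} orphaned (parent {r.parent_id})"
                )
            children[r.parent_id].append(r.cell_id)
        for cid, kids in children.items():
            kids.sort()
            if len(kids) > 3:
                raise TopologyError(f"lineage {lineage_id}: cell {cid} has {len(kids)} children")
        fusions: set[tuple[str, str]] = set()
        for r in recs:
            if r.fused_with is not None and r.fused_with in cells:
                fusions.add(tuple(sorted((r.cell_id, r.fused_with))))
        trees.append(
            LineageTree(
                lineage_id=lineage_id,
                condition=roots[0].condition,
                root=roots[0],
                cells=cells,
                children=children,
                fusion_links=sorted(fusions),
            )
        )
    return trees


def lineage_features(tree: LineageTree) -> dict[str, bool]:
    """Lineage-level abnormality flags.

    ``no_mitosis`` is true when no cell in the tree divided during the
    movie; ``mitotic_delay`` when any single mitosis lasted strictly more
    than 2 h; the remaining flags are true when any cell in the tree
    carries the corresponding per-cycle event.
    """
    recs = list(tree.cells.values())
    divided = any(tree.children.get(cid) for cid in tree.cells) or any(
        r.t_division is not None for r in recs
    )
    return {
        "no_mitosis": not divided,
        "mitotic_delay": any(
            r.mitotic_duration is not None and r.mitotic_duration > MITOTIC_DELAY_HOURS
            for r in recs
        ),
        "MN": any(r.micronuclei for r in recs),
        "bi_multi": any(r.bi_multi_nuclei for r in recs),
        "death": any(r.death for r in recs),
        "fading": any(r.fading for r in recs),
        "tripolar": any(r.tripolar for r in recs),
        "regression": any(r.regression for r in recs),
        "cell_fusion": any(r.fused_with is not None for r in recs) or bool(tree.fusion_links),
    }


def abnormality_percentages(trees: list[LineageTree]) -> pd.DataFrame:
    """Percent of lineages per condition showing each abnormality.

    One row per condition (sorted lexicographically), columns ``n_lineages``
    plus one percentage per feature in :data:`FEATURES`.  Conditions with no
    trees simply do not appear.
    """
    by_cond: dict[tuple[str, str, str], list[LineageTree]] = {}
    for t in trees:
        by_cond.setdefault(t.condition, []).append(t)
    rows = []
    for cond in sorted(by_cond):
        group = by_cond[cond]
        feats = [lineage_features(t) for t in group]
        row: dict = {
            "cell_line": cond[0],
            "treatment": cond[1],
            "stage": cond[2],
            "n_lineages": len(group),
        }
        for f in FEATURES:
            row[f] = 100.0 * sum(fd[f] for fd in feats) / len(group)
        rows.append(row)
    return pd.DataFrame(rows)
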