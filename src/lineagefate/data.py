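"""Tidy per-cell-cycle tables from live-cell lineage tracking.

One row of the canonical table is one observed cell cycle of one
mCitrine-positive cell: which lineage and cell it is, the experimental
condition (cell line, treatment, cell-cycle stage), its timing within the
movie, and the event flags scored for that cycle (micronucleus, death,
fusion, ...).  All times and durations are in hours.

The canonical schema (column names, hours, ``.`` decimal separator) is
defined here; tables with other column names can be loaded by passing a
column-mapping dict or config file to :func:`read_tidy`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CELL_LINES",
    "TREATMENTS",
    "STAGES",
    "COLUMNS",
    "CellRecord",
    "TidyDataset",
    "ValidationReport",
    "Violation",
    "SchemaError",
    "IntegrityError",
    "read_tidy",
    "write_tidy",
    "canonicalize",
    "validate",
    "load_column_map",
]

CELL_LINES = ("CTRL48", "SIS2-3")
TREATMENTS = ("mCit", "sgF11")
STAGES = ("1+x", "N+x")

#: Canonical column order of the tidy CSV.
COLUMNS = (
    "lineage_id",
    "cell_id",
    "parent_id",
    "cell_line",
    "treatment",
    "stage",
    "t_birth",
    "t_nebd",
    "t_division",
    "interphase_duration",
    "mitotic_duration",
    "micronuclei",
    "bi_multi_nuclei",
    "death",
    "fading",
    "tripolar",
    "regression",
    "fused_with",
    "censored",
)

_BOOL_COLUMNS = (
    "micronuclei",
    "bi_multi_nuclei",
    "death",
    "fading",
    "tripolar",
    "regression",
    "censored",
)
_TIME_COLUMNS = ("t_birth", "t_nebd", "t_division", "interphase_duration", "mitotic_duration")


class SchemaError(ValueError):
    """The table is missing a mandatory column or a value cannot be parsed."""


class IntegrityError(ValueError):
    """The table violates a structural rule (e.g. duplicate cell id)."""


@dataclass(frozen=True)
class CellRecord:
    """One observed cell cycle.

    ``cell_id`` uses path labels within the lineage ("a" root, "aa"/"ab"
    daughters, third daughter of a tripolar mitosis "?c").  A censored
    record is one whose cycle was truncated by the end of the movie; it
    never carries a division time, and it carries an interphase duration
    only if nuclear-envelope breakdown was still observed.
    """

    lineage_id: str
    cell_id: str
    parent_id: str | None
    cell_line: str
    treatment: str
    stage: str
    t_birth: float
    t_nebd: float | None = None
    t_division: float | None = None
    interphase_duration: float | None = None
    mitotic_duration: float | None = None
    micronuclei: bool = False
    bi_multi_nuclei: bool = False
    death: bool = False
    fading: bool = False
    tripolar: bool = False
    regression: bool = False
    fused_with: str | None = None
    censored: bool = False

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.cell_line, self.treatment, self.stage)

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


@dataclass
class TidyDataset:
    """An ordered collection of :class:`CellRecord` plus provenance.

    ``annotations`` preserves any non-canonical columns of the source file
    (row-aligned with ``records``).
    """

    records: list[CellRecord]
    provenance: dict = field(default_factory=dict)
    annotations: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lineage_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.lineage_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([_record_to_row(r) for r in self.records], columns=list(COLUMNS))
        if self.annotations is not None and len(self.annotations.columns):
            df = pd.concat([df, self.annotations.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "TidyDataset":
        return _dataset_from_frame(df, provenance or {})


@dataclass(frozen=True)
class Violation:
    lineage_id: str
    cell_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "violations": [v.__dict__ for v in self.violations],
            },
            indent=2,
        )


def _record_to_row(r: CellRecord) -> dict:
    row: dict = {}
    for c in COLUMNS:
        v = getattr(r, c)
        if c in _BOOL_COLUMNS:
            row[c] = int(v)
        else:
            row[c] = v
    return row


def _parse_bool(value, column: str, line: int) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no", "", "nan"}:
        return False
    raise SchemaError(f"line {line}: cannot parse boolean {column}={value!r}")


def _parse_time(value, column: str, line: int) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"line {line}: unparseable {column}={value!r}") from exc


def _parse_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a ``source_name = canonical_name`` key-value config file."""
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"column-map line not of form 'src = canonical': {raw!r}")
        src, dst = (part.strip() for part in line.split("=", 1))
        mapping[src] = dst
    return mapping


def _dataset_from_frame(df: pd.DataFrame, provenance: dict) -> TidyDataset:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]

    records: list[CellRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        d = dict(zip(df.columns, row))
        lineage_id = _parse_str(d["lineage_id"])
        cell_id = _parse_str(d["cell_id"])
        if lineage_id is None or cell_id is None:
            raise SchemaError(f"line {line}: empty lineage_id or cell_id")
        key = (lineage_id, cell_id)
        if key in seen:
            raise IntegrityError(f"duplicate (lineage_id, cell_id) = {key} at line {line}")
        seen.add(key)
        records.append(
            CellRecord(
                lineage_id=lineage_id,
                cell_id=cell_id,
                parent_id=_parse_str(d["parent_id"]),
                cell_line=str(d["cell_line"]).strip(),
                treatment=str(d["treatment"]).strip(),
                stage=str(d["stage"]).strip(),
                t_birth=_parse_time(d["t_birth"], "t_birth", line) or 0.0,
                t_nebd=_parse_time(d["t_nebd"], "t_nebd", line),
                t_division=_parse_time(d["t_division"], "t_division", line),
                interphase_duration=_parse_time(
                    d["interphase_duration"], "interphase_duration", line
                ),
                mitotic_duration=_parse_time(d["mitotic_duration"], "mitotic_duration", line),
                fused_with=_parse_str(d["fused_with"]),
                **{c: _parse_bool(d[c], c, line) for c in _BOOL_COLUMNS},
            )
        )
    annotations = df[extra].copy() if extra else None
    return TidyDataset(records=records, provenance=provenance, annotations=annotations)


def read_tidy(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> TidyDataset:
    """Read a tidy per-cell-cycle CSV into a :class:`TidyDataset`.

    Parameters
    ----------
    path
        Delimited text file (CSV, UTF-8) with a header row containing the
        canonical column names, or names translatable via ``column_map``.
    column_map
        Either a mapping ``{source_column: canonical_column}`` or the path of
        a key-value config file (``src = canonical`` per line).  Lets users
        load externally deposited source tables without renaming by hand.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map is not None:
        if not isinstance(column_map, Mapping):
            column_map = load_column_map(column_map)
        df = df.rename(columns=dict(column_map))
    return _dataset_from_frame(df, provenance={"source": str(path)})


def _format_number(x: float | None) -> str:
    if x is None:
        return ""
    if x == int(x):
        return str(int(x))
    return repr(round(float(x), 9))


def write_tidy(dataset: TidyDataset, path: str | Path | None = None) -> str:
    """Write the canonical tidy CSV; returns the text (and writes it if
    ``path`` is given).  Output is byte-deterministic for a given dataset."""
    buf = StringIO()
    cols = list(COLUMNS)
    ann = dataset.annotations
    if ann is not None:
        cols += list(ann.columns)
    buf.write(",".join(cols) + "\n")
    for i, r in enumerate(dataset.records):
        row = []
        for c in COLUMNS:
            v = getattr(r, c)
            if c in _BOOL_COLUMNS:
                row.append(str(int(v)))
            elif c in _TIME_COLUMNS:
                row.append(_format_number(v))
            else:
                row.append("" if v is None else str(v))
        if ann is not None:
            row += ["" if pd.isna(v) else str(v) for v in ann.iloc[i]]
        buf.write(",".join(row) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def canonicalize(path: str | Path) -> str:
    """Canonical text form of a tidy file: parse and re-emit.

    ``write_tidy(read_tidy(f))`` equals ``canonicalize(f)`` by construction
    and the map is idempotent, which is the round-trip contract tested for
    the I/O layer.
    """
    return write_tidy(read_tidy(path))


def _iter_lineages(records: Sequence[CellRecord]) -> Iterable[tuple[str, list[CellRecord]]]:
    by_lin: dict[str, list[CellRecord]] = {}
    for r in records:
        by_lin.setdefault(r.lineage_id, []).append(r)
    return by_lin.items()


def validate(dataset: TidyDataset) -> ValidationReport:
    """Check every record-level and lineage-level invariant.

    Violations are returned as data (with record coordinates), never raised:
    the caller decides whether a dirty dataset is fatal.
    """
    out: list[Violation] = []

    def bad(r: CellRecord, rule: str, msg: str) -> None:
        out.append(Violation(r.lineage_id, r.cell_id, rule, msg))

    for r in dataset.records:
        if r.cell_line not in CELL_LINES:
            bad(r, "cell_line", f"unknown cell_line {r.cell_line!r}")
        if r.treatment not in TREATMENTS:
            bad(r, "treatment", f"unknown treatment {r.treatment!r}")
        if r.stage not in STAGES:
            bad(r, "stage", f"unknown stage {r.stage!r}")
        if r.interphase_duration is not None and r.interphase_duration <= 0:
            bad(r, "positive_duration", f"interphase_duration={r.interphase_duration}")
        if r.mitotic_duration is not None and r.mitotic_duration <= 0:
            bad(r, "positive_duration", f"mitotic_duration={r.mitotic_duration}")
        if r.t_nebd is not None and r.t_birth > r.t_nebd + 1e-9:
            bad(r, "time_order", f"t_birth={r.t_birth} > t_nebd={r.t_nebd}")
        if r.t_nebd is not None and r.t_division is not None and r.t_nebd > r.t_division + 1e-9:
            bad(r, "time_order", f"t_nebd={r.t_nebd} > t_division={r.t_division}")
        if r.fading and not (r.cell_line == "SIS2-3" and r.treatment == "sgF11"):
            # fading is loss of the fusion reporter; only possible where the
            # reporter cassette was cut (SIS2-3 line under sgF11)
            bad(r, "fading_condition", "fading outside SIS2-3 sgF11")
        if r.censored and r.t_division is not None:
            bad(r, "censored_division", "censored record has a division time")

    for lineage_id, recs in _iter_lineages(dataset.records):
        ids = {r.cell_id for r in recs}
        roots = [r for r in recs if r.parent_id is None]
        if len(roots) != 1:
            for r in roots or recs[:1]:
                bad(r, "single_root", f"lineage {lineage_id} has {len(roots)} roots")
        stages = {r.stage for r in recs}
        if len(stages) > 1:
            bad(recs[0], "stage_constant", f"lineage {lineage_id} mixes stages {sorted(stages)}")
        for r in recs:
            if r.parent_id is not None and r.parent_id not in ids:
                bad(r, "orphan", f"parent {r.parent_id!r} not in lineage")
            # path-label redundancy: a child's id should extend its parent's
            if r.parent_id is not None and not r.cell_id.startswith(r.parent_id):
                bad(r, "path_label", f"cell_id {r.cell_id!r} does not extend parent {r.parent_id!r}")
    return ValidationReport(out)
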