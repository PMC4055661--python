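"""Census records, cell attributes, delimited-table I/O, and rate pools.

A :class:`PopulationRecord` is one taxon x map-cell census entry.  Each record
contributes at most one *change entity* to the rate pools:

* both censuses quantitative        -> a ``class_pair`` entity (the pair of
  size classes is pooled as a single unit),
* second census recorded extinct    -> a ``forced_extinction`` entity,
* otherwise, a decline score, if any -> a ``decline_score`` entity.

Pool 1 collects a taxon's entities across all its cells ("what happened here
may happen there"); pool 2 collects a cell's entities across all taxa in it
("what happened here will happen here again"); the global pool concatenates
everything and is the fallback for taxa with no change information of their
own.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .classes import EXTINCT_LABEL, RateClass, SizeClass

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationRecord",
    "CellAttributes",
    "ChangeEntity",
    "RatePools",
    "build_rate_pools",
    "read_census_table",
    "write_census_table",
    "read_cell_table",
    "write_cell_table",
]

CENSUS_COLUMNS = (
    "taxon_id",
    "cell_id",
    "size_first",
    "size_second",
    "decline_score",
    "pressures",
)
CELL_COLUMNS = ("cell_id", "pa_proportion", "core_proportion")


@dataclass(frozen=True)
class PopulationRecord:
    """One taxon x cell census entry."""

    taxon_id: str
    cell_id: str
    size_first: SizeClass | None = None
    size_second: SizeClass | None = None
    decline_score: RateClass | None = None
    pressures: frozenset = frozenset()

    def __post_init__(self):
        if (
            self.size_first is None
            and self.size_second is None
            and self.decline_score is None
        ):
            raise ValueError(
                f"record ({self.taxon_id}, {self.cell_id}) carries no "
                "size class or decline score"
            )

    @property
    def observed_extinct(self) -> bool:
        return self.size_second is not None and self.size_second.is_extinct


@dataclass(frozen=True)
class CellAttributes:
    """Protected-area coverage of one ~100-km2 map cell."""

    cell_id: str
    pa_proportion: float
    core_proportion: float

    def __post_init__(self):
        if not 0.0 <= self.pa_proportion <= 1.0:
            raise ValueError(f"pa_proportion out of [0,1]: {self.pa_proportion}")
        if not 0.0 <= self.core_proportion <= 1.0:
            raise ValueError(
                f"core_proportion out of [0,1]: {self.core_proportion}"
            )
        if self.core_proportion > self.pa_proportion + 1e-12:
            raise ValueError(
                f"cell {self.cell_id}: core_proportion "
                f"{self.core_proportion} exceeds pa_proportion "
                f"{self.pa_proportion}"
            )


@dataclass(frozen=True)
class ChangeEntity:
    """One record's evidence of decadal population change."""

    kind: str  # "class_pair" | "decline_score" | "forced_extinction"
    first_class: SizeClass | None = None
    second_class: SizeClass | None = None
    rate_class: RateClass | None = None

    @classmethod
    def from_record(cls, rec: PopulationRecord) -> "ChangeEntity | None":
        """The record's single change entity, or None if it carries none.

        A quantitative class pair takes precedence over a decline score; an
        observed extinction always yields a forced-extinction entity.
        """
        if rec.observed_extinct:
            return cls("forced_extinction")
        if (
            rec.size_first is not None
            and rec.size_second is not None
        ):
            return cls("class_pair", rec.size_first, rec.size_second)
        if rec.decline_score is not None:
            return cls("decline_score", rate_class=rec.decline_score)
        return None


@dataclass
class RatePools:
    """Taxon-wise (pool 1), cell-wise (pool 2) and global pools of entities."""

    pool1: dict = field(default_factory=dict)  # taxon_id -> [ChangeEntity]
    pool2: dict = field(default_factory=dict)  # cell_id -> [ChangeEntity]
    global_pool: list = field(default_factory=list)
    n_records: int = 0
    n_skipped: int = 0  # records without change information


def build_rate_pools(records: Iterable[PopulationRecord]) -> RatePools:
    """Assemble the three frequency-weighted pools of change entities."""
    pools = RatePools()
    for rec in records:
        pools.n_records += 1
        ent = ChangeEntity.from_record(rec)
        if ent is None:
            pools.n_skipped += 1
            continue
        pools.pool1.setdefault(rec.taxon_id, []).append(ent)
        pools.pool2.setdefault(rec.cell_id, []).append(ent)
        pools.global_pool.append(ent)
    if pools.n_skipped:
        logger.info(
            "%d of %d records carry no change information and were not pooled",
            pools.n_skipped,
            pools.n_records,
        )
    return pools


# ---------------------------------------------------------------------------
# delimited-table I/O (stdlib csv: the canonical dialect must round-trip
# byte-identically, which DataFrame writers do not guarantee)
# ---------------------------------------------------------------------------


def _parse_row(row: dict, lineno: int) -> PopulationRecord:
    try:
        sf = row.get("size_first") or None
        ss = row.get("size_second") or None
        dc = row.get("decline_score") or None
        pressures = frozenset(
            p for p in (row.get("pressures") or "").split(";") if p
        )
        return PopulationRecord(
            taxon_id=row["taxon_id"],
            cell_id=row["cell_id"],
            size_first=SizeClass.parse(sf, "first") if sf else None,
            size_second=SizeClass.parse(ss, "second") if ss else None,
            decline_score=RateClass.parse(dc) if dc else None,
            pressures=pressures,
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed census row at line {lineno}: {exc}") from exc


def read_census_table(path: str | Path) -> list[PopulationRecord]:
    """Read a census CSV into validated records, preserving row order.

    Raises on unknown class labels (naming the offending line) and on
    duplicate (taxon_id, cell_id) keys.  An empty table yields an empty list
    with a logged warning.
    """
    records: list[PopulationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("census table %s is empty", path)
            return records
        missing = set(("taxon_id", "cell_id")) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"census table {path} lacks columns {sorted(missing)}")
        for row in reader:
            rec = _parse_row(row, reader.line_num)
            key = (rec.taxon_id, rec.cell_id)
            if key in seen:
                raise ValueError(
                    f"duplicate (taxon_id, cell_id) key {key} at line "
                    f"{reader.line_num}"
                )
            seen.add(key)
            records.append(rec)
    if not records:
        logger.warning("census table %s contains no records", path)
    return records


def write_census_table(
    records: Sequence[PopulationRecord], path: str | Path
) -> None:
    """Write records in the canonical dialect read_census_table expects."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CENSUS_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.taxon_id,
                    rec.cell_id,
                    rec.size_first.label if rec.size_first else "",
                    rec.size_second.label if rec.size_second else "",
                    rec.decline_score.label if rec.decline_score else "",
                    ";".join(sorted(rec.pressures)),
                ]
            )


def read_cell_table(path: str | Path) -> list[CellAttributes]:
    """Read the per-cell protected-area coverage table."""
    cells: list[CellAttributes] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            try:
                cell = CellAttributes(
                    cell_id=row["cell_id"],
                    pa_proportion=float(row["pa_proportion"]),
                    core_proportion=float(row["core_proportion"]),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"malformed cell row at line {reader.line_num}: {exc}"
                ) from exc
            if cell.cell_id in seen:
                raise ValueError(f"duplicate cell_id {cell.cell_id!r}")
            seen.add(cell.cell_id)
            cells.append(cell)
    return cells


def write_cell_table(cells: Sequence[CellAttributes], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CELL_COLUMNS)
        for c in cells:
            writer.writerow([c.cell_id, format(c.pa_proportion, "g"), format(c.core_proportion, "g")])
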