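"""Data model and delimited-text I/O for cell lineage tables.

A lineage table holds one row per tracked cell:

    colony_id,cell_id,parent_id,birth_time_h,division_time_h,last_observed_h

Times are hours from the start of imaging and are expected to sit on the
frame grid of the time-lapse acquisition (20-minute frames by default).
An empty ``parent_id`` marks a colony founder, whose ``birth_time`` is
its first observation (attachment), not a division.  An empty
``division_time_h`` marks a cell never seen to divide.
``last_observed_h`` is when the cell left observation: its division, the
end of the video, or moving off-screen.

One file may hold many colonies; ``colony_id`` is the grouping key.
Trees are strictly binary: a cell either divides into exactly two
daughters or has none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

#: Default acquisition frame interval: one image every 20 minutes.
DEFAULT_FRAME_INTERVAL_H = 1.0 / 3.0

#: Absolute tolerance for comparing event times (hours).
TIME_TOLERANCE_H = 1e-6

LINEAGE_COLUMNS = (
    "colony_id",
    "cell_id",
    "parent_id",
    "birth_time_h",
    "division_time_h",
    "last_observed_h",
)


class LineageError(ValueError):
    """Base class for lineage-table validation failures."""


class LineageParseError(LineageError):
    """A lineage table could not be parsed row by row."""


class LineageStructureError(LineageError):
    """Parsed rows do not assemble into valid binary division trees."""


@dataclass(frozen=True)
class CellRecord:
    """One tracked cell.

    Parameters
    ----------
    colony_id, cell_id:
        Colony and within-colony cell identifiers.
    parent_id:
        Identifier of the mother cell, or ``None`` for a founder.
    birth_time:
        Hours from imaging start.  For a founder this is the first
        observation, for any other cell the mother's division time.
    division_time:
        Hours, or ``None`` if the cell was never seen to divide.  When
        present it must equal ``last_observed_time``.
    last_observed_time:
        Hours at which the cell left observation.
    """

    colony_id: str
    cell_id: str
    parent_id: str | None
    birth_time: float
    division_time: float | None
    last_observed_time: float

    def __post_init__(self) -> None:
        if not self.cell_id:
            raise LineageError("cell with empty id")
        if self.birth_time < 0:
            raise LineageError(f"cell {self.cell_id}: negative birth time")
        if self.last_observed_time < self.birth_time - TIME_TOLERANCE_H:
            raise LineageError(
                f"cell {self.cell_id}: last_observed_time precedes birth_time"
            )
        if self.division_time is not None:
            if self.division_time <= self.birth_time:
                raise LineageError(
                    f"cell {self.cell_id}: division_time not after birth_time"
                )
            if abs(self.division_time - self.last_observed_time) > TIME_TOLERANCE_H:
                raise LineageError(
                    f"cell {self.cell_id}: division_time differs from "
                    "last_observed_time"
                )

    @property
    def is_founder(self) -> bool:
        return self.parent_id is None

    @property
    def divided(self) -> bool:
        return self.division_time is not None

    @property
    def observed_duration(self) -> float:
        """Hours the cell was under observation after its birth."""
        return self.last_observed_time - self.birth_time


@dataclass
class LineageTree:
    """Rooted binary division tree for one founder cell.

    Invariants (checked by :func:`validate_tree`, not at construction,
    so that invalid trees can be represented and reported): exactly one
    founder; every non-founder's birth time equals its mother's division
    time; a divided cell has exactly two daughters and an undivided cell
    none; all cells reachable from the founder.
    """

    colony_id: str
    cells: tuple[CellRecord, ...]
    observation_end: float

    def __post_init__(self) -> None:
        self.cells = tuple(self.cells)

    # -- derived views -------------------------------------------------

    @cached_property
    def cell_map(self) -> dict[str, CellRecord]:
        return {c.cell_id: c for c in self.cells}

    @cached_property
    def children_map(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, tuple[str, ...]] = {c.cell_id: () for c in self.cells}
        for c in self.cells:
            if c.parent_id is not None and c.parent_id in out:
                out[c.parent_id] = out[c.parent_id] + (c.cell_id,)
        return out

    @property
    def founder(self) -> CellRecord:
        for c in self.cells:
            if c.is_founder:
                return c
        raise LineageStructureError(f"colony {self.colony_id}: no founder cell")

    def children_of(self, cell_id: str) -> tuple[CellRecord, ...]:
        return tuple(self.cell_map[i] for i in self.children_map.get(cell_id, ()))

    def leaves(self) -> tuple[CellRecord, ...]:
        return tuple(c for c in self.cells if not self.children_map.get(c.cell_id))

    def dividing_cells(self) -> tuple[CellRecord, ...]:
        return tuple(c for c in self.cells if c.divided)

    @property
    def n_divisions(self) -> int:
        return sum(1 for c in self.cells if c.divided)

    @cached_property
    def generation_map(self) -> dict[str, int]:
        """Forward generation of each cell (founder = 0).

        Assumes a validated tree; unreachable cells are absent.
        """
        gens = {self.founder.cell_id: 0}
        stack = [self.founder.cell_id]
        while stack:
            cid = stack.pop()
            for child in self.children_map.get(cid, ()):
                gens[child] = gens[cid] + 1
                stack.append(child)
        return gens


def validate_tree(tree: LineageTree) -> list[str]:
    """Check all :class:`LineageTree` invariants.

    Returns a list of human-readable violation descriptions, one per
    violated rule, each naming the offending cell.  An empty list means
    the tree is valid.  Validation never raises.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for c in tree.cells:
        if c.cell_id in seen:
            violations.append(f"duplicate id: {c.cell_id}")
        seen.add(c.cell_id)
        if c.colony_id != tree.colony_id:
            violations.append(f"colony-id mismatch: cell {c.cell_id}")
        if c.last_observed_time > tree.observation_end + TIME_TOLERANCE_H:
            violations.append(f"observation-window: cell {c.cell_id}")

    founders = [c for c in tree.cells if c.is_founder]
    if len(founders) != 1:
        violations.append(f"founder-count: found {len(founders)} founders")

    cell_map = {c.cell_id: c for c in tree.cells}
    n_children: dict[str, int] = {c.cell_id: 0 for c in tree.cells}
    for c in tree.cells:
        if c.parent_id is None:
            continue
        parent = cell_map.get(c.parent_id)
        if parent is None:
            violations.append(f"missing parent: cell {c.cell_id}")
            continue
        n_children[c.parent_id] += 1
        if parent.division_time is None:
            violations.append(f"undivided parent: cell {c.cell_id}")
        elif abs(c.birth_time - parent.division_time) > TIME_TOLERANCE_H:
            violations.append(f"time-consistency: cell {c.cell_id}")

    for c in tree.cells:
        n = n_children[c.cell_id]
        if c.divided and n != 2:
            violations.append(f"structure: cell {c.cell_id} has {n} daughter(s)")
        elif not c.divided and n != 0:
            violations.append(
                f"structure: undivided cell {c.cell_id} has {n} daughter(s)"
            )

    # Connectivity: every cell reachable from the (first) founder.
    if founders:
        children_map: dict[str, list[str]] = {c.cell_id: [] for c in tree.cells}
        for c in tree.cells:
            if c.parent_id in children_map:
                children_map[c.parent_id].append(c.cell_id)
        reached: set[str] = set()
        stack = [founders[0].cell_id]
        while stack:
            cid = stack.pop()
            if cid in reached:
                continue
            reached.add(cid)
            stack.extend(children_map.get(cid, ()))
        for c in tree.cells:
            if c.cell_id not in reached:
                violations.append(f"connectivity: cell {c.cell_id} unreachable")

    return violations


@dataclass
class ColonyDataset:
    """A collection of lineage trees sharing time units and acquisition.

    ``frame_interval`` is the imaging cadence in hours; all event times
    are expected to be integer multiples of it (within
    :data:`TIME_TOLERANCE_H`).
    """

    trees: tuple[LineageTree, ...]
    donor_id: str | None = None
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H

    def __post_init__(self) -> None:
        self.trees = tuple(self.trees)
        ids = [t.colony_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise LineageStructureError("duplicate colony ids in dataset")
        if self.frame_interval <= 0:
            raise LineageError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[LineageTree]:
        return iter(self.trees)

    def tree(self, colony_id: str) -> LineageTree:
        for t in self.trees:
            if t.colony_id == colony_id:
                return t
        raise KeyError(colony_id)

    @property
    def n_cells(self) -> int:
        return sum(len(t.cells) for t in self.trees)

    @property
    def n_divisions(self) -> int:
        return sum(t.n_divisions for t in self.trees)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tree in self.trees:
            for c in tree.cells:
                rows.append(
                    {
                        "colony_id": c.colony_id,
                        "cell_id": c.cell_id,
                        "parent_id": "" if c.parent_id is None else c.parent_id,
                        "birth_time_h": c.birth_time,
                        "division_time_h": (
                            "" if c.division_time is None else c.division_time
                        ),
                        "last_observed_h": c.last_observed_time,
                    }
                )
        return pd.DataFrame(rows, columns=list(LINEAGE_COLUMNS))


def validate_dataset(dataset: ColonyDataset) -> list[str]:
    """Validate every tree plus dataset-level rules (frame quantization)."""
    violations: list[str] = []
    for tree in dataset.trees:
        violations.extend(
            f"colony {tree.colony_id}: {v}" for v in validate_tree(tree)
        )
        for c in tree.cells:
            for t in (c.birth_time, c.division_time, c.last_observed_time):
                if t is None:
                    continue
                frames = t / dataset.frame_interval
                if abs(frames - round(frames)) * dataset.frame_interval > TIME_TOLERANCE_H:
                    violations.append(
                        f"colony {tree.colony_id}: quantization: cell {c.cell_id}"
                    )
                    break
    return violations


def _parse_time(value: str, column: str, row: int) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise LineageParseError(
            f"row {row}: cannot parse {column} value {value!r}"
        ) from exc


def read_lineage_table(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
    donor_id: str | None = None,
    observation_end: float | None = None,
) -> ColonyDataset:
    """Read and validate a lineage table.

    Parameters
    ----------
    path:
        CSV file with the documented column set.
    frame_interval:
        Acquisition cadence in hours; times are checked (not rounded)
        against this grid.
    observation_end:
        Video end time shared by all colonies.  When ``None`` it is
        inferred per colony as the latest ``last_observed_h``, which is
        exact whenever at least one cell of the colony was followed to
        the end of the video.

    Raises
    ------
    LineageParseError
        For malformed rows, missing columns, or duplicate cell ids.
    LineageStructureError
        When rows do not assemble into valid binary division trees
        (e.g. a cell with one daughter, or a daughter whose birth time
        differs from its mother's division time).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise LineageParseError(f"missing column(s): {', '.join(missing)}")

    by_colony: dict[str, list[CellRecord]] = {}
    seen_ids: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        colony_id = str(getattr(row, "colony_id")).strip()
        cell_id = str(getattr(row, "cell_id")).strip()
        parent_raw = str(getattr(row, "parent_id")).strip()
        if not cell_id:
            raise LineageParseError(f"row {i}: empty cell_id")
        key = (colony_id, cell_id)
        if key in seen_ids:
            raise LineageParseError(
                f"row {i}: duplicate cell id {cell_id!r} in colony {colony_id!r}"
            )
        seen_ids.add(key)
        birth = _parse_time(getattr(row, "birth_time_h"), "birth_time_h", i)
        division = _parse_time(getattr(row, "division_time_h"), "division_time_h", i)
        last = _parse_time(getattr(row, "last_observed_h"), "last_observed_h", i)
        if birth is None or last is None:
            raise LineageParseError(
                f"row {i}: birth_time_h and last_observed_h are required"
            )
        try:
            record = CellRecord(
                colony_id=colony_id,
                cell_id=cell_id,
                parent_id=parent_raw or None,
                birth_time=birth,
                division_time=division,
                last_observed_time=last,
            )
        except LineageError as exc:
            raise LineageParseError(f"row {i}: {exc}") from exc
        by_colony.setdefault(colony_id, []).append(record)

    trees = []
    for colony_id, records in by_colony.items():
        end = (
            observation_end
            if observation_end is not None
            else max(c.last_observed_time for c in records)
        )
        tree = LineageTree(colony_id=colony_id, cells=tuple(records), observation_end=end)
        violations = validate_tree(tree)
        if violations:
            raise LineageStructureError(
                f"colony {colony_id}: " + "; ".join(violations)
            )
        trees.append(tree)

    dataset = ColonyDataset(
        trees=tuple(trees), donor_id=donor_id, frame_interval=frame_interval
    )
    quant = [v for v in validate_dataset(dataset) if "quantization" in v]
    if quant:
        raise LineageStructureError("; ".join(quant))
    return dataset


def write_lineage_table(dataset: ColonyDataset, path: str | Path) -> None:
    """Write a dataset as CSV, re-readable bit-identically.

    Times are written with Python's shortest round-trip float
    representation, so ``read_lineage_table`` recovers them exactly and
    write-read-write is byte-stable.
    """
    df = dataset.to_frame()
    df.to_csv(Path(path), index=False)
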