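"""Cell-fate, division-type, and colony classification.

Fates follow the 48-hour rule used for tracked keratinocytes: a cell
that divides is proliferative (P); a cell followed for at least the
threshold without dividing is differentiated (D); a cell lost from
observation earlier is unknown (U) and is excluded downstream.  A
division is PP/PD/DD by its daughters' fates, or UNKNOWN if either
daughter is U.

Colonies are classified from their division timing and leaf fates:

* DIFFERENTIATING — no division within the final ``threshold`` hours of
  the observation window, every leaf with a known fate is D, and at
  least one leaf is D (the clone terminally differentiated);
* EXPANDING — at least one division within the final ``threshold``
  hours (the clone kept dividing through the whole window);
* UNCLASSIFIED — anything else (no divisions at all, or a quiescent
  tree whose leaf fates are all censored).

Generation indexing: founders are generation 0 and a division carries
the generation of the daughters it produces, so the first division of
the founder is generation 1.  Differentiating colonies are additionally
aligned backward from the terminal differentiation division (TD = 0,
earlier divisions negative); expanding colonies backward from the final
observed generation (FO = 0).  Alignment is per colony, offset by the
colony's maximum forward generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .lineage_io import (
    TIME_TOLERANCE_H,
    CellRecord,
    ColonyDataset,
    LineageTree,
)

#: Hours a non-dividing cell must be followed to be called differentiated.
DEFAULT_DIVISION_THRESHOLD_H = 48.0


class CellFate(str, Enum):
    P = "P"
    D = "D"
    U = "U"


class DivisionType(str, Enum):
    PP = "PP"
    PD = "PD"
    DD = "DD"
    UNKNOWN = "UNKNOWN"


class ColonyClass(str, Enum):
    EXPANDING = "EXPANDING"
    DIFFERENTIATING = "DIFFERENTIATING"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class GenerationIndex:
    """Forward and backward-aligned generation of one division.

    ``td_aligned`` is defined only in differentiating colonies (0 at the
    terminal differentiation division), ``fo_aligned`` only in expanding
    colonies (0 at the final observed generation).
    """

    forward: int
    td_aligned: int | None = None
    fo_aligned: int | None = None


def classify_cell_fate(
    cell: CellRecord, threshold: float = DEFAULT_DIVISION_THRESHOLD_H
) -> CellFate:
    """P if the cell divided, D if followed >= threshold without
    dividing, U otherwise."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if cell.divided:
        return CellFate.P
    if cell.observed_duration >= threshold - TIME_TOLERANCE_H:
        return CellFate.D
    return CellFate.U


def classify_division(
    mother: CellRecord, daughter_fates: tuple[CellFate, CellFate]
) -> DivisionType:
    """PP/PD/DD by daughter fates; UNKNOWN if any daughter is U.

    Order-insensitive: (P, D) and (D, P) are both PD.
    """
    if not mother.divided:
        raise ValueError(f"cell {mother.cell_id} did not divide")
    if len(daughter_fates) != 2:
        raise ValueError("a division has exactly two daughters")
    if CellFate.U in daughter_fates:
        return DivisionType.UNKNOWN
    n_p = sum(1 for f in daughter_fates if f is CellFate.P)
    return (DivisionType.DD, DivisionType.PD, DivisionType.PP)[n_p]


def classify_fates(
    tree: LineageTree, threshold: float = DEFAULT_DIVISION_THRESHOLD_H
) -> dict[str, CellFate]:
    return {c.cell_id: classify_cell_fate(c, threshold) for c in tree.cells}


def classify_divisions(
    tree: LineageTree, fates: Mapping[str, CellFate]
) -> dict[str, DivisionType]:
    """Division type per dividing cell id."""
    out = {}
    for mother in tree.dividing_cells():
        daughters = tree.children_of(mother.cell_id)
        pair = tuple(fates[d.cell_id] for d in daughters)
        out[mother.cell_id] = classify_division(mother, pair)  # type: ignore[arg-type]
    return out


def classify_colony(
    tree: LineageTree, threshold: float = DEFAULT_DIVISION_THRESHOLD_H
) -> ColonyClass:
    """Classify a colony as EXPANDING / DIFFERENTIATING / UNCLASSIFIED."""
    division_times = [c.division_time for c in tree.cells if c.divided]
    if not division_times:
        return ColonyClass.UNCLASSIFIED
    last_division = max(division_times)
    if last_division > tree.observation_end - threshold + TIME_TOLERANCE_H:
        return ColonyClass.EXPANDING
    fates = classify_fates(tree, threshold)
    leaf_fates = [fates[c.cell_id] for c in tree.leaves()]
    known = [f for f in leaf_fates if f is not CellFate.U]
    if known and all(f is CellFate.D for f in known):
        return ColonyClass.DIFFERENTIATING
    return ColonyClass.UNCLASSIFIED


def generation_indices(
    tree: LineageTree, colony_class: ColonyClass
) -> dict[str, GenerationIndex]:
    """Generation indices for every division (keyed by the mother id)."""
    gen_map = tree.generation_map
    forwards = {
        c.cell_id: gen_map[c.cell_id] + 1 for c in tree.dividing_cells()
    }
    if not forwards:
        return {}
    g_max = max(forwards.values())
    out = {}
    for cell_id, fwd in forwards.items():
        td = fwd - g_max if colony_class is ColonyClass.DIFFERENTIATING else None
        fo = fwd - g_max if colony_class is ColonyClass.EXPANDING else None
        out[cell_id] = GenerationIndex(forward=fwd, td_aligned=td, fo_aligned=fo)
    return out


@dataclass
class ColonyClassification:
    """All classification outputs for one colony."""

    colony_id: str
    colony_class: ColonyClass
    fates: dict[str, CellFate]
    division_types: dict[str, DivisionType]
    generations: dict[str, GenerationIndex]


def classify_tree(
    tree: LineageTree, threshold: float = DEFAULT_DIVISION_THRESHOLD_H
) -> ColonyClassification:
    """Run the full classification cascade on one colony."""
    fates = classify_fates(tree, threshold)
    colony_class = classify_colony(tree, threshold)
    return ColonyClassification(
        colony_id=tree.colony_id,
        colony_class=colony_class,
        fates=fates,
        division_types=classify_divisions(tree, fates),
        generations=generation_indices(tree, colony_class),
    )


def classify_dataset(
    dataset: ColonyDataset, threshold: float = DEFAULT_DIVISION_THRESHOLD_H
) -> dict[str, ColonyClassification]:
    return {t.colony_id: classify_tree(t, threshold) for t in dataset}
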