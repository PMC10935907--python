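"""Cell-cycle-duration statistics and group comparisons.

The cell cycle duration (CCD) of a tracked cell is the interval between
its birth (its mother's mitosis) and its own mitosis.  Founder
divisions carry no CCD, because the time from attachment to the first
division is not a complete cycle; CCDs therefore exist for the second
and subsequent divisions of a colony only.

Summaries report n, median with a distribution-free 95% confidence
interval (binomial order statistics), mean, and SEM, grouped by colony
class, by division type within class, by backward-aligned generation,
or restricted to the first *k* forward generations.

``compare_groups`` wraps the comparisons used for this kind of data:
Mann-Whitney rank sum (exact enumeration for small samples), Kruskal-
Wallis with Dunn's pairwise post-test, one-way ANOVA, and unpaired or
paired t tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fates import ColonyClass, ColonyClassification, DivisionType
from .lineage_io import ColonyDataset, LineageTree


class DegenerateDataError(ValueError):
    """A statistical routine received data it cannot meaningfully test
    (e.g. paired differences with zero variance)."""


@dataclass(frozen=True)
class DivisionRecord:
    """One mitosis with its CCD and classification context.

    ``ccd`` is ``None`` exactly when the dividing cell is a founder.
    """

    colony_id: str
    cell_id: str
    ccd: float | None
    division_type: DivisionType
    forward_gen: int
    td_aligned: int | None
    fo_aligned: int | None
    colony_class: ColonyClass


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-or-more-group comparison."""

    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    pairwise: tuple["TestResult", ...] | None = None
    details: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def compute_ccds(
    dataset: ColonyDataset,
    classifications: Mapping[str, ColonyClassification],
) -> list[DivisionRecord]:
    """One :class:`DivisionRecord` per observed division.

    Non-founder divisions carry ``ccd = division_time - birth_time``;
    founder divisions are emitted with ``ccd`` absent.  Cells never seen
    to divide produce no record.
    """
    records: list[DivisionRecord] = []
    for tree in dataset:
        cls = classifications[tree.colony_id]
        for mother in tree.dividing_cells():
            gen = cls.generations[mother.cell_id]
            ccd = None if mother.is_founder else mother.division_time - mother.birth_time
            records.append(
                DivisionRecord(
                    colony_id=tree.colony_id,
                    cell_id=mother.cell_id,
                    ccd=ccd,
                    division_type=cls.division_types[mother.cell_id],
                    forward_gen=gen.forward,
                    td_aligned=gen.td_aligned,
                    fo_aligned=gen.fo_aligned,
                    colony_class=cls.colony_class,
                )
            )
    return records


def records_frame(records: Iterable[DivisionRecord]) -> pd.DataFrame:
    rows = [
        {
            "colony_id": r.colony_id,
            "cell_id": r.cell_id,
            "ccd": np.nan if r.ccd is None else r.ccd,
            "division_type": r.division_type.value,
            "forward_gen": r.forward_gen,
            "td_aligned": r.td_aligned,
            "fo_aligned": r.fo_aligned,
            "colony_class": r.colony_class.value,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "colony_id",
            "cell_id",
            "ccd",
            "division_type",
            "forward_gen",
            "td_aligned",
            "fo_aligned",
            "colony_class",
        ],
    )


def median_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float] | None:
    """Distribution-free CI for the median via binomial order statistics.

    Picks the widest symmetric pair of order statistics whose exact
    coverage under Binomial(n, 1/2) is at least ``level``.  Returns
    ``None`` when n is too small for any valid interval (n < 6 at the
    95% level).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    alpha2 = (1.0 - level) / 2.0
    best = None
    for lo in range(1, n // 2 + 1):
        if stats.binom.cdf(lo - 1, n, 0.5) <= alpha2 + 1e-12:
            best = lo
        else:
            break
    if best is None:
        return None
    hi = n - best + 1
    return float(x[best - 1]), float(x[hi - 1])


def _summary_row(values: np.ndarray) -> dict:
    n = values.size
    row = {
        "n": int(n),
        "median": float(np.median(values)) if n else np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "mean": float(np.mean(values)) if n else np.nan,
        "sem": float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
    }
    ci = median_ci(values) if n else None
    if ci is not None:
        row["ci_low"], row["ci_high"] = ci
    return row


def _qualifying(records: Iterable[DivisionRecord]) -> list[DivisionRecord]:
    return [
        r
        for r in records
        if r.ccd is not None and r.division_type is not DivisionType.UNKNOWN
    ]


def summarize_ccd(
    records: Iterable[DivisionRecord],
    group_by: str = "colony_class",
    k: int = 3,
) -> pd.DataFrame:
    """Per-group CCD summary table.

    ``group_by`` is one of ``colony_class``, ``division_type``
    (division type within colony class), ``aligned_generation``
    (backward-aligned generation within colony class; TD-aligned for
    differentiating colonies, FO-aligned for expanding ones), or
    ``first_k_generations`` (colony class, restricted to forward
    generations <= ``k``).  Founder divisions and divisions with an
    unknown daughter are excluded throughout.
    """
    recs = _qualifying(records)
    groups: dict[tuple, list[float]] = {}
    if group_by == "colony_class":
        keys = ["colony_class"]
        for r in recs:
            groups.setdefault((r.colony_class.value,), []).append(r.ccd)
    elif group_by == "division_type":
        keys = ["colony_class", "division_type"]
        for r in recs:
            groups.setdefault(
                (r.colony_class.value, r.division_type.value), []
            ).append(r.ccd)
    elif group_by == "aligned_generation":
        keys = ["colony_class", "aligned_gen"]
        for r in recs:
            aligned = (
                r.td_aligned
                if r.colony_class is ColonyClass.DIFFERENTIATING
                else r.fo_aligned
            )
            if aligned is None:
                continue
            groups.setdefault((r.colony_class.value, aligned), []).append(r.ccd)
    elif group_by == "first_k_generations":
        keys = ["colony_class"]
        for r in recs:
            if r.forward_gen <= k:
                groups.setdefault((r.colony_class.value,), []).append(r.ccd)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for key in sorted(groups):
        row = dict(zip(keys, key))
        row.update(_summary_row(np.asarray(groups[key], dtype=float)))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=keys + ["n", "median", "ci_low", "ci_high", "mean", "sem"]
    )


def fate_proportions_by_generation(
    dataset: ColonyDataset,
    classifications: Mapping[str, ColonyClassification],
    alignment: str = "forward",
    colony_class: ColonyClass | None = None,
) -> pd.DataFrame:
    """Proportion of P and D daughters produced at each generation.

    ``alignment`` is ``forward`` (founder's division = generation 1),
    ``td`` (backward from the terminal differentiation division of
    differentiating colonies), or ``fo`` (backward from the final
    observed generation of expanding colonies).  Unknown daughters are
    excluded from the denominator.  Reports both pooled proportions and
    the across-colony mean with SEM.
    """
    if alignment not in ("forward", "td", "fo"):
        raise ValueError(f"unknown alignment {alignment!r}")
    per_colony: dict[tuple[str, int], list[int]] = {}  # (colony, gen) -> [nP, nD]
    for tree in dataset:
        cls = classifications[tree.colony_id]
        if colony_class is not None and cls.colony_class is not colony_class:
            continue
        for mother in tree.dividing_cells():
            gen = cls.generations[mother.cell_id]
            idx = {
                "forward": gen.forward,
                "td": gen.td_aligned,
                "fo": gen.fo_aligned,
            }[alignment]
            if idx is None:
                continue
            for daughter in tree.children_of(mother.cell_id):
                fate = cls.fates[daughter.cell_id]
                if fate.value == "U":
                    continue
                counts = per_colony.setdefault((tree.colony_id, idx), [0, 0])
                counts[0 if fate.value == "P" else 1] += 1

    by_gen: dict[int, dict] = {}
    for (colony_id, gen), (n_p, n_d) in per_colony.items():
        entry = by_gen.setdefault(gen, {"n_p": 0, "n_d": 0, "per_colony_p": []})
        entry["n_p"] += n_p
        entry["n_d"] += n_d
        entry["per_colony_p"].append(n_p / (n_p + n_d))

    rows = []
    for gen in sorted(by_gen):
        e = by_gen[gen]
        n = e["n_p"] + e["n_d"]
        pc = np.asarray(e["per_colony_p"], dtype=float)
        rows.append(
            {
                "generation": gen,
                "n_daughters": n,
                "prop_p": e["n_p"] / n,
                "prop_d": e["n_d"] / n,
                "n_colonies": pc.size,
                "mean_prop_p": float(pc.mean()),
                "sem_prop_p": (
                    float(pc.std(ddof=1) / math.sqrt(pc.size)) if pc.size > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "generation",
            "n_daughters",
            "prop_p",
            "prop_d",
            "n_colonies",
            "mean_prop_p",
            "sem_prop_p",
        ],
    )


def growth_curve(tree: LineageTree) -> pd.DataFrame:
    """Number of cells at each forward generation of one colony."""
    gens = tree.generation_map
    counts: dict[int, int] = {}
    for g in gens.values():
        counts[g] = counts.get(g, 0) + 1
    rows = [
        {"generation": g, "n_cells": counts[g]} for g in sorted(counts)
    ]
    return pd.DataFrame(rows, columns=["generation", "n_cells"])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

#: Largest combined sample size for which the rank-sum test enumerates
#: the exact null distribution of U.
EXACT_RANKSUM_MAX_N = 12


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all labelings.

    Uses midranks, so ties are handled exactly.  The two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))`` under the permutation
    null.
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    us = np.array(
        [
            ranks[list(idx)].sum() - offset
            for idx in combinations(range(n1 + n2), n1)
        ]
    )
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def _ranksum(x: np.ndarray, y: np.ndarray) -> TestResult:
    if len(x) + len(y) <= EXACT_RANKSUM_MAX_N:
        u, p = _ranksum_exact(x, y)
        return TestResult(
            method="ranksum_exact",
            statistic=u,
            p_value=p,
            group_sizes=(len(x), len(y)),
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(
        method="ranksum_normal",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(len(x), len(y)),
    )


def _dunn_pairwise(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> tuple[TestResult, ...]:
    """Dunn's z tests on mean ranks after Kruskal-Wallis, with tie
    correction; p reported unadjusted and Bonferroni-adjusted."""
    all_values = np.concatenate(groups)
    n_total = all_values.size
    ranks = stats.rankdata(all_values)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.nan
        p = float(2.0 * stats.norm.sf(abs(z))) if not math.isnan(z) else np.nan
        out.append(
            TestResult(
                method="dunn",
                statistic=float(z),
                p_value=p,
                group_sizes=(int(groups[i].size), int(groups[j].size)),
                details={
                    "pair": (labels[i], labels[j]),
                    "p_bonferroni": min(1.0, p * m) if not math.isnan(p) else np.nan,
                },
            )
        )
    return tuple(out)


def compare_groups(
    samples: Sequence[Sequence[float]],
    method: str,
    labels: Sequence[str] | None = None,
) -> TestResult:
    """Compare two or more groups of values.

    ``method`` is one of ``ranksum`` (two-group Mann-Whitney; exact
    enumeration when the combined n is at most
    :data:`EXACT_RANKSUM_MAX_N`, tie-corrected normal approximation
    otherwise), ``kruskal_dunn`` (Kruskal-Wallis, with Dunn's pairwise
    post-tests attached as ``result.pairwise``), ``anova`` (one-way),
    ``t_unpaired``, or ``t_paired``.  All p-values are two-sided.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    labels = list(labels) if labels is not None else [
        f"group{i + 1}" for i in range(len(groups))
    ]
    sizes = tuple(int(g.size) for g in groups)

    if method == "ranksum":
        if len(groups) != 2:
            raise ValueError("ranksum compares exactly two groups")
        return _ranksum(groups[0], groups[1])
    if method == "kruskal_dunn":
        stat, p = stats.kruskal(*groups)
        return TestResult(
            method="kruskal_wallis",
            statistic=float(stat),
            p_value=float(p),
            group_sizes=sizes,
            pairwise=_dunn_pairwise(groups, labels),
        )
    if method == "anova":
        stat, p = stats.f_oneway(*groups)
        return TestResult(
            method="anova", statistic=float(stat), p_value=float(p), group_sizes=sizes
        )
    if method == "t_unpaired":
        if len(groups) != 2:
            raise ValueError("t_unpaired compares exactly two groups")
        stat, p = stats.ttest_ind(groups[0], groups[1])
        return TestResult(
            method="t_unpaired",
            statistic=float(stat),
            p_value=float(p),
            group_sizes=sizes,
        )
    if method == "t_paired":
        if len(groups) != 2:
            raise ValueError("t_paired compares exactly two groups")
        if groups[0].size != groups[1].size:
            raise ValueError("paired test requires equal group lengths")
        diffs = groups[0] - groups[1]
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise DegenerateDataError("paired differences have zero variance")
        stat, p = stats.ttest_rel(groups[0], groups[1])
        return TestResult(
            method="t_paired",
            statistic=float(stat),
            p_value=float(p),
            group_sizes=sizes,
        )
    raise ValueError(f"unknown method {method!r}")
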