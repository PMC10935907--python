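"""Ergodic-principle cell-cycle phase inference.

In an asynchronous, steadily cycling population, the fraction of cells
observed in a given phase equals the fraction of the total cycle that
a single cell spends in that phase.  Two consequences are used here:

* given a population's phase proportions (G1/S/G2M) and its total cycle
  duration, each phase duration is the proportion times the total;
* under the additional assumption that S-phase duration is the same in
  two populations, the ratio of their total cycle durations is the
  inverse ratio of their S-phase fractions (a population cycling twice
  as slowly shows half as many cells in S).

Inputs are per-sample phase-proportion tables (e.g. from transcriptomic
phase scoring) and S-phase labeling counts (EdU-positive cells among
cycling, Ki67-positive cells); a 1-hour EdU pulse is treated as a
point-in-time snapshot of S-phase occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccd_stats import DegenerateDataError

_SUM_TOLERANCE = 1e-9

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class PhaseProportions:
    """Fractions of one sample's cycling cells in each phase."""

    sample_id: str
    group: str
    f_g1: float
    f_s: float
    f_g2m: float

    def __post_init__(self) -> None:
        for name, f in (("f_g1", self.f_g1), ("f_s", self.f_s), ("f_g2m", self.f_g2m)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        total = self.f_g1 + self.f_s + self.f_g2m
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"phase fractions sum to {total}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_g1, self.f_s, self.f_g2m)


@dataclass(frozen=True)
class PhaseDurations:
    """Absolute phase lengths in hours; they sum to the total CCD."""

    t_g1: float
    t_s: float
    t_g2m: float

    def __post_init__(self) -> None:
        for name, t in (("t_g1", self.t_g1), ("t_s", self.t_s), ("t_g2m", self.t_g2m)):
            if t < 0:
                raise ValueError(f"{name}={t} is negative")

    @property
    def t_total(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2m

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t_g1, self.t_s, self.t_g2m)


@dataclass(frozen=True)
class StainCounts:
    """S-phase labeling counts for one cycling population."""

    sample_id: str
    population: str
    n_cycling: int
    n_edu_pos: int

    def __post_init__(self) -> None:
        if self.n_cycling < 0:
            raise ValueError("n_cycling must be nonnegative")
        if not 0 <= self.n_edu_pos <= self.n_cycling:
            raise ValueError("need 0 <= n_edu_pos <= n_cycling")


def phase_durations_from_proportions(
    props: PhaseProportions, t_total: float
) -> PhaseDurations:
    """Decompose a total cycle duration into phase lengths.

    Each phase duration is its observed proportion times ``t_total``;
    the durations sum exactly to ``t_total``.
    """
    if t_total <= 0:
        raise ValueError("t_total must be positive")
    return PhaseDurations(
        t_g1=props.f_g1 * t_total,
        t_s=props.f_s * t_total,
        t_g2m=props.f_g2m * t_total,
    )


def relative_ccd_from_s_fractions(f_s_a: float, f_s_b: float) -> float:
    """Ratio of total cycle durations T_b / T_a from S-phase fractions.

    Assumes both populations spend the same absolute time in S, so a
    smaller S fraction means a proportionally longer cycle.
    """
    for name, f in (("f_s_a", f_s_a), ("f_s_b", f_s_b)):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"{name}={f} must be in (0, 1]")
    return f_s_a / f_s_b


def s_fraction_from_stains(counts: StainCounts) -> float:
    """Fraction of cycling cells in S phase (EdU+ / cycling)."""
    if counts.n_cycling == 0:
        raise ValueError("no cycling cells")
    return counts.n_edu_pos / counts.n_cycling


def aggregate_phase_durations(
    per_sample: Sequence[tuple[PhaseDurations, PhaseDurations]],
) -> pd.DataFrame:
    """Across-sample aggregation of paired phase-duration inferences.

    ``per_sample`` holds one ``(group A, group B)`` pair per sample.
    Returns one row per phase with each group's mean and SEM and a
    two-sided paired t test of the per-sample differences.
    """
    if len(per_sample) < 2:
        raise ValueError("need at least two paired samples")
    a = np.array([p[0].as_tuple() for p in per_sample], dtype=float)
    b = np.array([p[1].as_tuple() for p in per_sample], dtype=float)
    rows = []
    for i, phase in enumerate(PHASES):
        diffs = a[:, i] - b[:, i]
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise DegenerateDataError(
                f"paired {phase} differences have zero variance"
            )
        t_stat, p = stats.ttest_rel(a[:, i], b[:, i])
        n = a.shape[0]
        rows.append(
            {
                "phase": phase,
                "n": n,
                "mean_a": float(a[:, i].mean()),
                "sem_a": float(a[:, i].std(ddof=1) / math.sqrt(n)),
                "mean_b": float(b[:, i].mean()),
                "sem_b": float(b[:, i].std(ddof=1) / math.sqrt(n)),
                "t_statistic": float(t_stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["phase", "n", "mean_a", "sem_a", "mean_b", "sem_b",
                 "t_statistic", "p_value"],
    )


# ---------------------------------------------------------------------------
# Delimited-text input
# ---------------------------------------------------------------------------

def read_phase_proportions(path: str | Path) -> list[PhaseProportions]:
    """Read ``sample_id,group,f_G1,f_S,f_G2M`` CSV."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "f_G1", "f_S", "f_G2M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    return [
        PhaseProportions(
            sample_id=str(r.sample_id),
            group=str(r.group),
            f_g1=float(r.f_G1),
            f_s=float(r.f_S),
            f_g2m=float(r.f_G2M),
        )
        for r in df.itertuples(index=False)
    ]


def read_stain_counts(path: str | Path) -> list[StainCounts]:
    """Read ``sample_id,population,n_cycling,n_edu_pos`` CSV."""
    df = pd.read_csv(path)
    required = {"sample_id", "population", "n_cycling", "n_edu_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    return [
        StainCounts(
            sample_id=str(r.sample_id),
            population=str(r.population),
            n_cycling=int(r.n_cycling),
            n_edu_pos=int(r.n_edu_pos),
        )
        for r in df.itertuples(index=False)
    ]
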