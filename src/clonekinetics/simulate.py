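"""Seeded branching-process generators for lineage data.

The generator emulates clonal growth of primary keratinocytes under
time-lapse imaging.  Two founder phenotypes are modeled:

* **SC** (stem-like, expanding): every division's outcome is drawn from
  a constant PP/PD/DD law (defaults 88.4/7.2/4.4%), and each
  proliferative cell's cycle duration is lognormal with a
  division-type-specific median (defaults 19/22/26 h for PP/PD/DD) —
  so colonies keep expanding near-exponentially.
* **CP** (committed-progenitor, differentiating): cycle durations are
  lognormal with median 30 h; each colony draws a target generation
  count N uniformly from {1..7}, and each daughter born at generation g
  differentiates with probability q(g) = (g/N)^k, reaching certainty at
  generation N, so the clone terminally differentiates within N
  generations.

Cycle-duration draws for cells destined to divide are truncated at the
48-h boundary that downstream fate classification uses, mirroring the
observation that when a further division occurs it almost always does
so within 48 h.  Event times are quantized to the acquisition frame
grid (20-minute frames by default); internally the simulator works in
integer frame counts so that a daughter's birth time is bit-identical
to its mother's division time.

Censoring has three sources: the end of the observation window;
memoryless per-cell off-screen loss (rate per hour); and, mimicking the
finite microscope field where a grown colony cannot be tracked
exhaustively, a per-colony tracking capacity — once the number of
concurrently tracked live cells reaches it, newborn cells are recorded
but immediately lost to follow-up.  Loss at birth is independent of a
cell's destined fate, so classified division-outcome proportions and
cycle-duration samples remain unbiased under capacity censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from heapq import heappush, heappop
from typing import Sequence

import numpy as np
from scipy import stats

from .ergodic import StainCounts
from .fates import DEFAULT_DIVISION_THRESHOLD_H
from .lineage_io import (
    DEFAULT_FRAME_INTERVAL_H,
    CellRecord,
    ColonyDataset,
    LineageTree,
)

SC = "SC"
CP = "CP"

_OUTCOMES = ("PP", "PD", "DD")


@dataclass(frozen=True)
class StemParams:
    """Division-outcome law and cycle durations of SC founders."""

    p_pp: float = 0.884
    p_pd: float = 0.072
    p_dd: float = 0.044
    ccd_median_by_type: dict = field(
        default_factory=lambda: {"PP": 19.0, "PD": 22.0, "DD": 26.0}
    )
    ccd_log_sd: float = 0.25

    def __post_init__(self) -> None:
        total = self.p_pp + self.p_pd + self.p_dd
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities sum to {total}, not 1")
        if min(self.p_pp, self.p_pd, self.p_dd) < 0:
            raise ValueError("outcome probabilities must be nonnegative")
        if any(m <= 0 for m in self.ccd_median_by_type.values()):
            raise ValueError("CCD medians must be positive")
        if self.ccd_log_sd < 0:
            raise ValueError("ccd_log_sd must be nonnegative")


@dataclass(frozen=True)
class ProgenitorParams:
    """Cycle duration and differentiation schedule of CP founders.

    A colony draws its target generation count N uniformly from
    {1..max_generations}; a daughter at generation g differentiates
    with probability q(g) = (g/N)^differentiation_exponent (so q(N)=1).
    """

    ccd_median: float = 30.0
    ccd_log_sd: float = 0.25
    max_generations: int = 7
    differentiation_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.ccd_median <= 0:
            raise ValueError("ccd_median must be positive")
        if self.ccd_log_sd < 0:
            raise ValueError("ccd_log_sd must be nonnegative")
        if self.max_generations < 1:
            raise ValueError("max_generations must be at least 1")
        if self.differentiation_exponent <= 0:
            raise ValueError("differentiation_exponent must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters for a simulated imaging experiment.

    Defaults mirror the study conditions: 65 colonies per experiment of
    which ~20% expand, a 16-day (384-h) window imaged every 20 min,
    founder attachment-to-first-division lag uniform on 0-24 h, a small
    off-screen loss hazard, and a tracking capacity of 100 concurrent
    cells per colony (``None`` disables capacity censoring).
    """

    seed: int = 0
    n_colonies: int = 65
    p_sc: float = 0.2
    window: float = 384.0
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H
    founder_first_division_delay: float | tuple[float, float] = (0.0, 24.0)
    offscreen_rate: float = 0.002
    tracking_capacity: int | None = 100
    ccd_upper: float = DEFAULT_DIVISION_THRESHOLD_H
    sc_params: StemParams = field(default_factory=StemParams)
    cp_params: ProgenitorParams = field(default_factory=ProgenitorParams)
    donor_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be nonnegative")
        if not 0.0 <= self.p_sc <= 1.0:
            raise ValueError("p_sc must be in [0, 1]")
        if self.window < 0:
            raise ValueError("window must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.offscreen_rate < 0:
            raise ValueError("offscreen_rate must be nonnegative")
        if self.tracking_capacity is not None and self.tracking_capacity < 1:
            raise ValueError("tracking_capacity must be positive or None")
        if self.ccd_upper <= 0:
            raise ValueError("ccd_upper must be positive")


def _draw_ccd(
    rng: np.random.Generator, median: float, log_sd: float, upper: float
) -> float:
    """Lognormal cycle duration, truncated above at ``upper`` hours."""
    if log_sd == 0.0:
        return min(median, upper)
    mu = math.log(median)
    if upper == math.inf:
        return float(rng.lognormal(mu, log_sd))
    f_upper = stats.norm.cdf((math.log(upper) - mu) / log_sd)
    u = rng.uniform(0.0, f_upper)
    return float(math.exp(mu + log_sd * stats.norm.ppf(u)))


def _delay(rng: np.random.Generator, spec: float | tuple[float, float]) -> float:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return float(spec)


def simulate_colony(
    config: SimulationConfig,
    founder_type: str,
    rng: np.random.Generator,
    colony_id: str = "c1",
) -> LineageTree:
    """Simulate one colony as a branching process.

    ``founder_type`` is ``"SC"`` or ``"CP"``.  Event times are integer
    multiples of ``config.frame_interval``; the returned tree's
    ``observation_end`` is the window end.
    """
    if founder_type not in (SC, CP):
        raise ValueError(f"founder_type must be {SC!r} or {CP!r}")
    frame = config.frame_interval
    window_f = int(math.floor(config.window / frame + 1e-9))
    sc, cp = config.sc_params, config.cp_params
    outcome_probs = (sc.p_pp, sc.p_pd, sc.p_dd)
    n_target = (
        int(rng.integers(1, cp.max_generations + 1)) if founder_type == CP else 0
    )

    records: list[CellRecord] = []
    heap: list[tuple[int, int, tuple]] = []
    seq = 0
    next_id = 1
    alive = 0

    def diff_prob(gen: int) -> float:
        if gen >= n_target:
            return 1.0
        return (gen / n_target) ** cp.differentiation_exponent

    def make_cell(
        birth_f: int, gen: int, destined_p: bool, parent_id: str | None,
        extra_delay: float = 0.0,
    ) -> None:
        nonlocal seq, next_id, alive
        cell_id = str(next_id)
        next_id += 1
        birth_h = birth_f * frame
        at_capacity = (
            config.tracking_capacity is not None
            and alive >= config.tracking_capacity
            and parent_id is not None
        )
        if at_capacity:
            # Recorded but lost to follow-up immediately (field-of-view limit).
            records.append(
                CellRecord(colony_id, cell_id, parent_id, birth_h, None, birth_h)
            )
            return
        if config.offscreen_rate > 0:
            loss_f = birth_f + int(
                math.floor(rng.exponential(1.0 / config.offscreen_rate) / frame)
            )
        else:
            loss_f = np.iinfo(np.int64).max

        division_f = None
        outcome = None
        if destined_p:
            if founder_type == SC:
                outcome = _OUTCOMES[rng.choice(3, p=outcome_probs)]
                median = sc.ccd_median_by_type[outcome]
                log_sd = sc.ccd_log_sd
            else:
                median = cp.ccd_median
                log_sd = cp.ccd_log_sd
            ccd = _draw_ccd(rng, median, log_sd, config.ccd_upper)
            division_f = max(
                birth_f + 1, int(round((birth_h + extra_delay + ccd) / frame))
            )

        end_f = min(loss_f, window_f)
        divides = destined_p and division_f is not None and division_f <= end_f
        if divides:
            end_f = division_f
        end_h = end_f * frame
        records.append(
            CellRecord(
                colony_id,
                cell_id,
                parent_id,
                birth_h,
                end_h if divides else None,
                end_h,
            )
        )
        alive += 1
        heappush(heap, (end_f, seq, (cell_id, gen, divides, outcome)))
        seq += 1

    founder_delay = _delay(rng, config.founder_first_division_delay)
    make_cell(0, 0, True, None, extra_delay=founder_delay)

    while heap:
        division_f, _, (cell_id, gen, divides, outcome) = heappop(heap)
        alive -= 1
        if not divides:
            continue
        # Daughter fates:
        if founder_type == SC:
            if outcome == "PP":
                fates = [True, True]
            elif outcome == "DD":
                fates = [False, False]
            else:
                fates = [True, False]
                if rng.random() < 0.5:
                    fates.reverse()
        else:
            q = diff_prob(gen + 1)
            fates = [rng.random() >= q, rng.random() >= q]
        for destined_p in fates:
            make_cell(division_f, gen + 1, destined_p, cell_id)

    return LineageTree(
        colony_id=colony_id, cells=tuple(records), observation_end=window_f * frame
    )


def simulate_experiment(config: SimulationConfig) -> ColonyDataset:
    """Simulate a multi-colony imaging experiment.

    Founder phenotypes are Bernoulli(``p_sc``); each colony runs on an
    independent child stream of the seed, so results are reproducible
    and invariant to colony order.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_colonies + 1)
    type_rng = np.random.default_rng(children[0])
    is_sc = type_rng.random(config.n_colonies) < config.p_sc
    trees = []
    for i in range(config.n_colonies):
        colony_rng = np.random.default_rng(children[i + 1])
        trees.append(
            simulate_colony(
                config,
                SC if is_sc[i] else CP,
                colony_rng,
                colony_id=f"c{i + 1:03d}",
            )
        )
    return ColonyDataset(
        trees=tuple(trees),
        donor_id=config.donor_id,
        frame_interval=config.frame_interval,
    )


def simulate_phase_population(
    t_g1: float,
    t_s: float,
    t_g2m: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Sample an asynchronous population's phase occupancy.

    Each cell's cycle position is uniform on [0, T_total); its phase is
    the interval (G1, then S, then G2M) containing the position.
    Returns counts per phase.
    """
    durations = (t_g1, t_s, t_g2m)
    if any(d < 0 for d in durations):
        raise ValueError("phase durations must be nonnegative")
    total = sum(durations)
    if total <= 0:
        raise ValueError("phase durations must sum to a positive total")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = rng.uniform(0.0, total, size=n)
    bounds = np.cumsum(durations)[:2]
    idx = np.searchsorted(bounds, positions, side="right")
    counts = np.bincount(idx, minlength=3)
    return {"G1": int(counts[0]), "S": int(counts[1]), "G2M": int(counts[2])}


@dataclass(frozen=True)
class StainPopulationSpec:
    """Ground truth for one stained population."""

    population: str
    s_fraction: float
    n_cycling: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_fraction <= 1.0:
            raise ValueError("s_fraction must be in [0, 1]")
        if self.n_cycling < 0:
            raise ValueError("n_cycling must be nonnegative")


@dataclass(frozen=True)
class StainSimConfig:
    """Configuration for simulated S-phase labeling counts."""

    seed: int = 0
    populations: tuple[StainPopulationSpec, ...] = ()
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


def simulate_stain_counts(config: StainSimConfig) -> list[StainCounts]:
    """Binomial EdU+ counts per sample and population, seeded."""
    rng = np.random.default_rng(config.seed)
    out = []
    for j in range(config.n_samples):
        sample_id = f"s{j + 1}"
        for spec in config.populations:
            n_pos = int(rng.binomial(spec.n_cycling, spec.s_fraction))
            out.append(
                StainCounts(
                    sample_id=sample_id,
                    population=spec.population,
                    n_cycling=spec.n_cycling,
                    n_edu_pos=n_pos,
                )
            )
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of a simulation configuration."""
    d = asdict(config)
    if isinstance(d["founder_first_division_delay"], tuple):
        d["founder_first_division_delay"] = list(d["founder_first_division_delay"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    """Inverse of :func:`config_to_dict` (accepts partial dicts)."""
    d = dict(d)
    if "sc_params" in d and isinstance(d["sc_params"], dict):
        d["sc_params"] = StemParams(**d["sc_params"])
    if "cp_params" in d and isinstance(d["cp_params"], dict):
        d["cp_params"] = ProgenitorParams(**d["cp_params"])
    if isinstance(d.get("founder_first_division_delay"), list):
        d["founder_first_division_delay"] = tuple(d["founder_first_division_delay"])
    return SimulationConfig(**d)
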