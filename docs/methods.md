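# Methods

## Data model

A lineage table has one row per tracked cell: colony id, cell id,
parent id (empty for the founder), birth time, division time (empty if
the cell was never seen to divide), and the time the cell left
observation. Times are hours from the start of imaging and must sit on
the acquisition frame grid (default one frame per 20 min, i.e. 1/3 h)
within 1e-6 h; quantization is *checked*, never enforced by rounding,
so a malformed table fails loudly instead of being silently repaired.
Trees are strictly binary — a division has exactly two daughters — and
a daughter's birth time must equal its mother's division time exactly.
A founder's birth time is its first observation (attachment), not a
division, so the interval from attachment to the first division is not
a cell cycle; cell-cycle durations (CCDs) exist only for the second and
subsequent divisions of a colony.

Writing uses the shortest round-trip float representation, so
write→read is the identity and write→read→write is byte-stable. When a
table is read back, the per-colony video end is inferred as the latest
last-observed time unless passed explicitly; this is exact whenever at
least one cell of the colony was followed to the end of the video, and
is the one piece of information a lineage table does not carry.

## Classification

* **Cell fate.** P if the cell divided; D if followed at least 48 h
  (configurable) without dividing; U (unknown) if censored earlier. The
  48-h threshold reflects the empirical fact that when a further
  division occurs it almost always occurs within 48 h of the previous
  one, so "has not divided in 48 h" is a reliable proxy for "will not
  divide". Raising the threshold can only move cells from D to U.
* **Division type.** PP/PD/DD from the two daughters' fates,
  order-insensitive; UNKNOWN if either daughter is U. UNKNOWN divisions
  are excluded from outcome proportions and CCD summaries.
* **Colony class.** EXPANDING if any division falls in the final 48 h
  of the window (the clone was still dividing when observation ended);
  DIFFERENTIATING if no division falls there, every leaf with a known
  fate is D, and at least one leaf is D; UNCLASSIFIED otherwise
  (including trees with no divisions). The differentiating rule is the
  operational definition of terminal differentiation; the expanding
  rule is its complement on division timing. UNCLASSIFIED absorbs
  degenerate or heavily censored clones rather than forcing a call.
* **Generations.** Founders are generation 0; a division carries the
  generation of the daughters it produces (the founder's division is
  generation 1). Backward alignment subtracts the colony's maximum
  forward generation: the terminal differentiation division (TD) of a
  differentiating colony is 0, earlier divisions −1, −2, …; expanding
  colonies are aligned the same way from the final observed generation
  (FO). Alignment is per colony, not per branch: colonies with
  different depths are compared at the same distance from their end
  state.

## CCD statistics

Summaries report n, median, a distribution-free 95% CI for the median,
mean, and SEM. The CI uses binomial order statistics: the widest
symmetric pair of order statistics whose exact coverage under
Binomial(n, 1/2) is ≥ 95%; below n = 6 no such interval exists and the
CI is reported absent. Fate proportions per generation are reported
both pooled across colonies and as the across-colony mean ± SEM of
per-colony proportions (the latter is what error bars over "(n)
colonies analyzed" describe); U daughters are excluded from
denominators.

Group comparisons: the two-group rank-sum test enumerates the exact
permutation null of U (midranks, so ties are exact) when the combined
sample is ≤ 12, and otherwise uses the tie-corrected normal
approximation; the two-sided exact p is min(1, 2·min(P(U ≤ u),
P(U ≥ u))). Kruskal-Wallis is followed by Dunn's pairwise z tests on
mean ranks with tie correction, reported both unadjusted and
Bonferroni-adjusted (the adjustment convention is a choice; both are
given). One-way ANOVA and unpaired/paired t tests cover the
mean-comparison cases; a paired test on zero-variance differences is a
degenerate-input error rather than a silent NaN.

## Ergodic phase inference

For an asynchronous, steadily cycling population, the fraction of
cells in a phase equals the phase's share of total cycle time, so
T_phase = f_phase × T_total, and the durations conserve the total
exactly. Under the additional assumption that S-phase duration is
equal between two populations, T_b / T_a = f_S(a) / f_S(b) from
S-labeling fractions alone. A 1-h EdU pulse is treated as a
point-in-time snapshot of S occupancy (no pulse-length correction) —
appropriate because the pulse is short relative to S phase itself.
Inference is per sample first, then aggregated across samples as
mean ± SEM with two-sided paired t tests per phase; holoclone samples
get the expanding-colony CCD and meroclone/paraclone samples the
differentiating-colony CCD, kept as separate comparisons rather than
pooled (any pooling weight across the two committed groups would be an
extra assumption).

## Synthetic-data generator

The generator emulates the study design that the analysis assumes:
single founders imaged every 20 min for a default 16-day (384-h)
window, with two founder phenotypes.

* **SC (expanding) founders.** Every division outcome is drawn from a
  constant PP/PD/DD law, default 0.884/0.072/0.044. A proliferative
  cell's CCD is lognormal with a median tied to the outcome of its own
  division — defaults 19 h (PP), 22 h (PD), 26 h (DD) — and log-sd
  0.25, truncated above at the 48-h fate boundary (with median 19 and
  log-sd 0.25 the untruncated tail above 48 h is ≈ 1%, consistent with
  ">97% of divisions within 48 h"). Mean tracked offspring per
  division is 2(p_PP + p_PD/2) ≈ 1.84 > 1: supercritical growth.
* **CP (differentiating) founders.** CCDs are lognormal, median 30 h,
  log-sd 0.25, truncated at 48 h. Each colony draws a target
  generation count N uniformly from {1..7}; a daughter born at
  generation g differentiates with probability q(g) = (g/N)^k
  (default k = 2), reaching 1 at generation N, so every uncensored CP
  clone terminally differentiates within at most 7 generations with a
  rising share of D daughters — a parametric stand-in for the observed
  rising differentiation probability, not a mechanistic claim.
* **Founder lag.** The founder's first division occurs after an
  attachment lag drawn uniform on 0–24 h (cells attach and recover
  after plating; the exact lag is unobserved) plus a CCD draw.
* **Censoring.** Three mechanisms: (1) end of window — cells alive at
  the window end are censored there; (2) off-screen loss — a
  memoryless per-cell hazard, default 0.002/h, producing occasional
  mid-video unknowns; (3) tracking capacity — once a colony's
  concurrently tracked live cells reach a cap (default 100), newborns
  are recorded but immediately lost to follow-up. The capacity models
  the finite microscope field and the practical impossibility of
  exhaustively tracking a large colony; because loss at birth is
  independent of a cell's destined fate, it censors P and D daughters
  symmetrically and leaves classified outcome proportions and CCD
  samples unbiased, while keeping a 384-h supercritical colony
  (otherwise ~10^5 divisions) at a tractable size. Setting the
  capacity to `None` and the off-screen rate to 0 recovers the
  pure branching process.
* **Internals.** The simulator works in integer frame counts, so a
  daughter's birth time is bit-identical to its mother's division time
  and all times sit exactly on the frame grid; a division is pushed at
  least one frame after birth. Each colony runs on an independent
  child stream of the experiment seed (`numpy` `SeedSequence.spawn`),
  so outputs are reproducible and invariant to colony order.

Phase populations are sampled by placing each cell uniformly on
[0, T_total) and reading off the phase interval; staining counts are
binomial draws at a configured true S fraction.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline consumes: binary
trees with frame-quantized times, two colony phenotypes with distinct
CCD scales and outcome laws, terminal differentiation schedules, and
realistic censoring patterns. It does not model space (colony
geometry, migration, field-of-view edges), density effects, G0
dormancy, or per-donor heterogeneity; off-screen loss is i.i.d. per
cell rather than spatially correlated. Passing recovery tests
therefore demonstrates that the *analysis* is correct and unbiased
under the stated generative assumptions — not that those assumptions
exhaust real imaging data.

### Observed-vs-generative proportions

Two selection effects make the *observed* PP share among classified
divisions exceed the generative p_PP by ~1.5–2 percentage points at
the default parameters. First, because PP divisions have the shortest
CCDs, divisions *completed* by any finite horizon over-represent PP.
Second, near the end of the window a P daughter resolves its fate in
~19 h (by dividing) while a D daughter needs the full 48 h, so
late-window censoring discards relatively more D-informative
divisions. Both effects operate identically in real windowed tracking
data, so the pipeline's recovered ~90% PP from a 0.884 generative law
is faithful behavior, not an estimator defect; the parameter-recovery
tests budget for it.

## Problem sizes and numerical choices

Recovery checks use 200 simulated colonies per phenotype (≈ 2 × 10^4
classified divisions for the expanding arm), enough that Monte-Carlo
error on a pooled median is well inside the ±5% check while an
end-to-end run stays under a minute. Phase-population checks use
n = 10^5 with 3-binomial-SE bands. Medians inherit the 1/3-h frame
granularity, so recovered medians land on the frame grid (e.g. 19.0 or
19.33). Event-time comparisons use a 1e-6-h tolerance; phase-fraction
sums are validated to 1e-6; p-values are validated to lie in [0, 1].

## Known limitations

* Censored cycles are excluded (per the U rule), not modeled by
  survival methods; with heavy censoring the observed-CCD sample is
  mildly biased toward shorter cycles.
* Colony video end inferred from a table is a lower bound when every
  cell of a colony was lost before the video ended; pass the window
  explicitly when it is known.
* The CP differentiation schedule q(g) = (g/N)^k is one convenient
  family; k is exposed but only its default is exercised by the
  recovery suite.
* The expanding/differentiating dichotomy is operational; biological
  intermediates (e.g. meroclone-like behavior) appear as occasional
  early-terminating colonies under the SC outcome law rather than as a
  third phenotype.
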