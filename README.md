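# clonekinetics

Lineage-tree analytics and cell-cycle inference for clonal cultures of
primary cells tracked by time-lapse imaging.

When single keratinocytes are plated and imaged for days to weeks, each
founder gives rise to a clone whose division history can be recorded as
a binary lineage tree. Two behaviors dominate: *expanding* colonies
that keep dividing near-exponentially through the whole observation
window (stem-cell-founded), and *differentiating* colonies whose cells
progressively stop dividing and terminally differentiate
(committed-progenitor-founded). `clonekinetics` implements the
analysis downstream of tracking:

* **Lineage I/O** — read, validate, and write per-cell lineage tables
  (CSV; one row per tracked cell with birth, division, and
  last-observed times on the imaging frame grid).
* **Fate classification** — the 48-hour rule: a cell that divides is
  proliferative (P), a cell followed ≥ 48 h without dividing is
  differentiated (D), cells censored earlier are unknown (U). Each
  division is PP/PD/DD by its daughters' fates; colonies are classified
  expanding/differentiating/unclassified from division timing and leaf
  fates, and divisions get forward and backward-aligned generation
  indices (TD = terminal differentiation division, FO = final observed
  generation).
* **Cell-cycle-duration (CCD) statistics** — a cell's CCD is the
  interval between two consecutive mitoses, T = t(division) − t(birth);
  founder divisions carry no CCD. Summaries report n, median with a
  distribution-free 95% CI (binomial order statistics), mean and SEM by
  colony class, division type, aligned generation, or early
  generations, plus Mann-Whitney (exact for small n), Kruskal-Wallis
  with Dunn post-tests, ANOVA, and t tests.
* **Ergodic phase inference** — in an asynchronous population the
  fraction of cells in a phase equals that phase's share of the cycle:
  T_phase = f_phase × T_total; and under equal S-phase duration,
  T_b / T_a = f_S(a) / f_S(b) from S-labeling (EdU) fractions.
* **Synthetic data** — a seeded branching-process simulator that
  generates lineage tables, asynchronous phase populations, and
  binomial staining counts with the statistical structure the analysis
  assumes, so the whole pipeline is testable without imaging data.

## Worked example

Simulate a 30-colony experiment and analyze it end to end:

```sh
echo '{"n_colonies": 30, "seed": 7}' > config.json
clonekinetics simulate --config config.json --out lineage.csv
clonekinetics analyze --lineage lineage.csv --out analysis
```

The analysis log and `analysis/report.json` contain (this exact run):

```
census: {'DIFFERENTIATING': 21, 'EXPANDING': 5, 'UNCLASSIFIED': 4}
ccd_by_class:
  DIFFERENTIATING  n=124  median=29.83  95% CI (28.0, 31.0)   mean=29.89  sem=0.55
  EXPANDING        n=653  median=19.33  95% CI (19.0, 20.0)   mean=19.77  sem=0.19
ranksum (expanding vs differentiating): U=8017.5, p = 1.4e-45
```

Read: of 30 simulated founders, 5 formed expanding colonies and 21
differentiating ones (4 were censored too early to classify). Pooled
over non-founder divisions with both daughter fates known, expanding
colonies cycle with median ~19 h versus ~30 h in differentiating
colonies — recovering the generative parameters — and the rank-sum test
separates the two distributions decisively. The report also tabulates
PP/PD/DD shares, fate proportions per backward-aligned generation,
growth curves, and the full test battery (`analysis/report.md` is the
human-readable rendering).

Ergodic inference runs from phase-proportion tables (e.g. produced by
transcriptomic phase scoring) and optional staining counts:

```sh
clonekinetics ergodic --phases phases.csv --ccd-exp 19 --ccd-dif 30 \
    --stains stains.csv --out ergodic_out
```

For example, an S-phase proportion of 0.746 on a 19-h cycle gives
T_S = 0.746 × 19 = 14.2 h.

## Layout

```
src/clonekinetics/
  lineage_io.py   data model + CSV I/O + validation
  fates.py        P/D/U, PP/PD/DD, colony classes, generation indices
  ccd_stats.py    CCD tables, fate proportions, growth curves, tests
  ergodic.py      phase-duration inference from proportions and stains
  simulate.py     branching-process and phase-population generators
  report.py       end-to-end orchestration, JSON/Markdown reports
  cli.py          `clonekinetics` command line
docs/methods.md   model, parameters, and design notes
```
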