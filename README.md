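# hitseries

Assay-promiscuity analysis of screening compounds via matched molecular
series.

High-throughput screening corpora report, per compound, active/inactive
calls over hundreds of primary assays. A few compounds hit far more
often than the sub-percent background — through colloidal aggregation,
PAINS chemistry and other interference mechanisms, or through genuine
multi-target activity. Judging single compounds is fragile; judging
*analog series* is not: analogs sharing one substitution site provide
mutual controls. `hitseries` is a library (plus a thin CLI) for exactly
that analysis, aimed at cheminformaticians and medicinal chemists
working with PubChem-style activity exports.

## What it computes

For a compound *c* with definite primary outcomes, the **hit rate** is
`hr(c) = n_active(c) / n_tested(c)`. The **selection cascade** keeps
compounds with `n_tested > Q1` of the assay-frequency distribution, then
derives the high-hit-rate threshold as the median hit rate of the
subpopulation with `hr >= 1.0%`, and keeps compounds strictly above it
(all cutoffs can be fixed instead).

Selected structures are fragmented at single acyclic bonds under
retrosynthetic (RECAP-style) or permissive exocyclic rules. Compounds
sharing a cut core with different substituents form a **matched
molecular pair (MMP)**; the union of compounds pairing on one core is a
**matched molecular series (MMS)** — an analog series varied at one
site. After redundancy removal, each series *S* with per-member tested
sets `T_m` and active sets `A_m` gets three parameters over primary
assays:

    HR(S)         = |∪ A_m| / |∪ T_m|          series hit rate
    overlap(S)    = |∩ T_m| / |∪ T_m|          assay overlap
    inconsistent(S) = |{a ∈ ∩T_m : mixed outcomes}| / |∩ T_m|

plus a target-based hit rate over annotated assays, Borda rank fusion
across the three criteria, and PAINS/aggregator interference flags with
a series-level census. A synthetic-data module generates libraries with
planted analog series and activity matrices with planted promiscuity,
so every stage is testable with known ground truth.

## Worked example

`examples/04_series_parameters.py` profiles a two-analog series where A
was tested in assays 1–10 (active in 1) and B in assays 6–15 (active in
6 and 7):

```text
assay union 15, active assays 3
series hit rate   HR = 3/15 = 0.200
assay overlap        = 5/15 = 0.333
inconsistent assays  = 2/5 = 0.400
```

The union of 15 assays saw 3 with activity (HR 20%); the analogs share
5 assays, a third of their union, so their histories are moderately
comparable; and in 2 of those 5 shared assays one analog was active
while the other was not.

`examples/06_full_pipeline.py` runs everything on a synthetic bundle
(3 planted series of sizes 2/3/4 among 60 decoys) and prints the run
report, ending in:

```text
series before/after dedup: 3/3
unique series compounds:   9
series size histogram:     2:1, 3:1, 4:1
interference census:       clean=3, with_aggregator=0, with_both=0, with_pains=0
```

— the planted design recovered exactly, with no interference inputs so
all series are clean. The other examples cover simulation, hit-rate
selection, series extraction and PAINS/aggregator flagging; each prints
a short explanation of its numbers.

The same stages are available from the shell:

```bash
hitseries simulate --n-series 5 --n-decoys 50 --seed 1 --out work/
hitseries run --structures work/library.smi --activity work/activity.tsv \
              --rules exocyclic --out work/results
```

## Layout

- `src/hitseries/` — `chem` (standardization), `activity` (profiles,
  cascade), `fragmentation` + `mms` (MMP/MMS), `profiling` (series
  parameters, rank fusion), `interference` (PAINS/aggregators),
  `synthetic` (generators), `pipeline` (orchestration), `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — definitions, conventions, generator design and
  known limitations.
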