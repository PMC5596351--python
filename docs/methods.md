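# Methods

## Problem and model

Large screening corpora (the shape of a PubChem BioAssay extract) record,
for each compound, outcomes over hundreds of primary single-dose assays
and a smaller number of confirmatory dose-response assays. A compound's
*hit rate* is the fraction of its definite primary outcomes that are
active calls. Most compounds sit in a sub-percent "bulk"; a small tail is
active far more often, through assay interference (aggregation, PAINS
chemistry, fluorescence, reactivity) or genuine multi-target pharmacology.

This package implements a data-driven pipeline for isolating and
characterizing that tail at the level of *analog series* rather than
single compounds:

1. **Selection cascade.** Keep compounds tested in strictly more primary
   assays than the lower quartile of the assay-frequency distribution;
   within those, take the subpopulation with hit rate >= the bulk upper
   bound (1.0% by default); set the high-hit-rate threshold to the median
   hit rate of that subpopulation; keep compounds strictly above it.
   All three cutoffs can instead be fixed by the caller.
2. **Series extraction.** Each selected structure is fragmented at single
   acyclic bonds (RECAP-style retrosynthetic bond types by default, or
   all exocyclic single bonds). Two compounds sharing a cut core with
   different substituents form a matched molecular pair (MMP); the union
   of all compounds pairing on one core is a matched molecular series
   (MMS) — an analog series varied at exactly one site. Redundant series
   (strict member subsets, or duplicate member sets on a smaller core)
   are removed.
3. **Series parameters.** Over primary assays only: series hit rate
   HR = |active assays| / |assay union|, assay overlap =
   |assay intersection| / |assay union|, and the inconsistent fraction =
   the proportion of shared assays where some members are active and
   others inactive. Series are prioritized by Borda rank fusion
   (descending HR and overlap, ascending inconsistency; mean of the three
   tied-average ranks).
4. **Interference flags.** Members are screened against a PAINS
   substructure catalog (any dialect, loaded from file; the 480-family
   RDKit reference collection is exposed for convenience) and against an
   aggregator reference list by exact canonical-structure identity after
   salt stripping and charge neutralization.

## Definitions, conventions and tie-breaks

- **Outcome resolution.** Duplicate records for one (compound, assay,
  stage) resolve to active if any record is active, else inactive if any
  is inactive, else inconclusive. Motivated by repositories that export
  several result versions per assay; configurable in principle by
  pre-filtering the record stream.
- **Inconclusive outcomes** stay in the matrix but are excluded from both
  the numerator and denominator of every hit rate, and from tested sets.
  A consequence is that every member has a definite call in every shared
  assay, so the inconsistency evaluation never meets an inconclusive.
- **Strictness.** Frequency threshold and high-hit-rate threshold are
  strict (`>`); the bulk bound is inclusive (`>=`). A compound sitting
  exactly on the frequency or high threshold is excluded.
- **Quartiles** use linear interpolation (the numpy/R-type-7 default).
  Data-derived thresholds depend on this convention; it is the one most
  statistical software defaults to. Boxplot whiskers are the most extreme
  data points within 1.5 x IQR of the box, clipped to the box edges when
  no data point lies beyond them inside the fence.
- **Size restrictions** (defaults: substituent <= 13 heavy atoms,
  exchanged-substituent difference <= 8, core at least 2x the
  substituent) follow conventions of the matched-molecular-pair
  literature; they are reconstructions, configurable, not measurements.
- **Single cut only.** Multi-cut MMPs are excluded: a series is defined
  by *one* substitution site.
- **Attachment points** are single labeled dummy atoms; cores are
  canonicalized with the label included, so cores differing only in
  attachment position are distinct series.
- **Series splitting.** Within one core the MMP relation may be
  incomplete (pairwise size-difference violations). Emitted series are
  the maximal cliques of the compliant-pair graph (>= 2 members), largest
  first, ties broken on sorted member ids — so every member pair of every
  emitted series is itself a valid MMP.
- **Redundancy removal.** Strict member-subset series are dropped; among
  identical member sets the largest core (heavy atoms) wins, with the
  lexicographically smaller core string as the deterministic tie-break.
- **Undefined values.** A series with an empty assay intersection has an
  undefined (null, never 0) inconsistent fraction and ranks last on that
  criterion — no shared assays means no evidence of consistency. A series
  touching no target-annotated assay has an undefined target-based hit
  rate.
- **Target-based hit rate** restricts to annotated primary assays; a
  target is tested/active when any member is tested/active in any assay
  of that target. Unannotated assays (e.g. cell-based readouts) remain in
  all assay-based statistics.
- **Confirmatory consistency** of a compound set is the fraction of its
  compounds with at least one confirmatory-stage active, with no
  requirement that the confirmatory assay match the primary target — the
  literal "also active in a confirmatory assay" reading.
- **Stereochemistry** is preserved by canonicalization; stereoisomers are
  distinct compounds.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every stage has exactly checkable inputs.

- **Assay frequency** is a discretized lognormal clipped to
  [50, n_assays]; the defaults (median 347, sigma 1.18) reproduce a
  corpus whose median compound saw a few hundred primary assays with
  ~95% above 50. Tests that need tight statistical control use a
  narrower law (median 400, sigma 0.25) so that frequency variation does
  not dominate the quantity under test; problem sizes there (2000
  compounds, 600 assays, 100 planted pairs) were chosen as the smallest
  that give stable 3-sigma margins.
- **Activity** is per-assay Bernoulli: 0.4% background, 6% for planted
  promiscuous compounds. These are the package's standard study
  conditions for calibration tests.
- **Tested-set overlap** within a planted series: members share one
  frequency draw f and a common base set of size `overlap_level x f`,
  plus independent private draws. At overlap 1 the tested sets are
  identical by construction. For k members the induced expected Jaccard
  overlap is approximately o / (k - (k-1)o) — plus coincidental private
  overlap when f approaches the assay universe — so `overlap_level` is a
  monotone dial, exactly 1 at its upper end, not a calibrated Jaccard
  target elsewhere.
- **Confirmatory records**: each compound with >= 1 primary active gets
  one confirmatory record, active with probability 0.93. The draw is per
  compound, not per primary active: the quantity being emulated (the
  fraction of high-hit-rate compounds that are also confirmatory-active)
  is compound-level, and per-active draws would push that fraction to ~1
  for any compound with tens of actives.
- **Decoys** are fused aromatic ring systems (5 frames, up to 3 aza
  substitutions; 373 unique structures) with no acyclic single bond, so
  they admit no single-cut fragmentation at all. This makes recovery
  experiments exact: a decoy can never share a core with anything.
  The cost is realism — real inactive compounds do fragment and produce
  inactive series; the generator's recovery guarantee says nothing about
  core collisions in real chemistry.
- **Planted series for recovery experiments** should use the
  `RING_SCAFFOLDS` subset (attachment directly on a fused ring system).
  The phenylene-linker scaffolds (benzamide, anisole, ...) can
  legitimately collide across plans when one plan's substituent recreates
  another plan's fixed group (anisole + cyano is benzonitrile + methoxy);
  that is correct MMP behavior, not an extraction error.

Passing tests on this generator demonstrate algorithmic correctness
(exact set algebra, exact recovery, statistical calibration of rates),
not performance on real screening data: real data adds correlated assay
panels, batch effects, non-independent outcomes within targets, and far
richer chemistry than a 29-scaffold vocabulary.

## Selection-cascade calibration

Calibration experiments run the cascade with *fixed* thresholds
(tested > 50 assays — the extensively-tested floor; bulk 1.0%; high
1.8%), because a sensitivity experiment with *derived* thresholds is
answering a different question: the derived frequency cutoff removes the
bottom quartile regardless of activity (frequency and promiscuity are
independent, by design), and the derived high threshold median-splits the
above-bulk population — so derived-threshold recall is bounded near 40%
by construction, which example 02 demonstrates deliberately. With fixed
thresholds and the standard conditions, a promiscuous compound at 6% over
~400 assays clears 1.8% with overwhelming probability
(P[Bin(400, 0.06) <= 7] is ~1e-4), and a background compound at 0.4%
essentially never does, so measured sensitivity is ~100%.

## Determinism

All randomness flows through numpy Generators seeded explicitly; tested
sets are emitted sorted; all tabular and JSON outputs are stable-sorted
with fixed float formatting. Two pipeline runs with identical inputs and
configuration produce byte-identical reports (asserted in the test
suite). Timings go to the log stream only, never into report artifacts.

## Known limitations

- RECAP bond-type SMARTS are a reconstruction of the classical rule set;
  laboratory implementations differ in detail, which shifts which bonds
  are cleavable and hence the series census. The permissive "exocyclic"
  rule set is provided for transparent, rule-independent analyses.
- Aggregator matching is exact-identity only; near-neighbor (<100%
  similarity) aggregator analogy is out of scope.
- No dose-response modeling: confirmatory assays contribute a binary
  active/inactive flag only.
- Absolute interference counts from published large-scale analyses are
  not reproducible without the exact source extract and filter catalogs;
  the package validates identities and mechanisms instead.
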