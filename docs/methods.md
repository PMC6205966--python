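# Methods

`panscan` analyzes the repertoire of c-di-GMP turnover proteins — GGDEF-domain
diguanylate cyclases (DGCs), EAL- and HD-GYP-domain phosphodiesterases (PDEs) —
across a set of bacterial genomes, in the style of genus-wide comparative
studies of *Streptomyces*. This note documents the models, conventions and
design choices; it states only what the test suite and the acceptance script
themselves compute.

## Pairwise alignment and identity

All identities come from one scoring scheme: BLOSUM62, gap open 10, gap
extension 0.5 (`panscan.align`). Two modes are used: local (Smith–Waterman)
for domain scans and best-hit searches, and semiglobal (global with cost-free
terminal gaps) for whole-protein identity. Percent identity is the number of
identical aligned residue pairs divided by the number of aligned columns
*including internal gaps but excluding terminal overhangs* — a deliberate
approximation of the global-identity convention of whole-protein ortholog
clustering tools, stated once and tested (a copy of a 300-residue protein
with exactly 90 substituted positions measures exactly 70%). Coverage is the
fraction of reference residues inside the aligned core. Ties between optimal
alignments resolve to the left-most traceback, so results are deterministic.

## Domain detection and active-site grading

Domains are found by local alignment against packaged exemplar domain
sequences (one per kind), with thresholds `min_identity = 30%` and
`min_coverage = 60%` of the reference domain. This replaces database-driven
domain annotation (COG/SMART); the COG identifiers conventionally attached to
these families (COG2199, COG2200, COG3437, …) are kept as metadata labels.
The exemplar sequences shipped with the package are synthetic (see below).

Active sites are read through the alignment's column map:

* **GGDEF A-site** (consensus `GG[D/E]EF`): 0 mismatches → *intact* (DGC
  active); exactly 1 mismatch (e.g. `GGDDF`) → *atypical* (detected, no
  activity assigned — the catalytic status of such single-substitution
  variants is genuinely open); ≥2 mismatches (e.g. the engineered `ALLEF`,
  `AADEF`) → *degenerate*. The adjacent `RxxD` inhibitory I-site (ending five
  residues upstream of the first A-site glycine) is extracted and reported but
  never gates an activity call, since feedback inhibition does not bear on
  whether the enzyme is active.
* **EAL**: *intact* requires the `E-x-L` motif, conservation of the second
  catalytic glutamate, and ≥75% conservation over the annotated catalytic
  positions; a conserved motif with a partially eroded catalytic shell is
  *atypical*; loss of the motif or of the key glutamate is *degenerate*.
* **HD-GYP**: *intact* requires the H…D metal-binding dyad plus all three
  G, Y, P residues; GYP conserved with a broken dyad is *atypical*; any GYP
  loss is *degenerate*.

Per-protein classification: an intact GGDEF makes a DGC, an intact EAL or
HD-GYP makes a PDE, both make a bifunctional DGC/PDE candidate, domains
present but none intact make a *degenerate* protein, and no domains at all
make *none*. The rendered activity label collapses degenerate and
domain-free proteins to "none", matching how such tables are usually printed.
Architecture strings are rendered N→C (`10TM-GGDEF-degEAL`), with a `nTM-`
prefix when two or more predicted transmembrane segments are present.

Transmembrane segments use the classical Kyte–Doolittle sliding window
(window 19, cutoff 1.6, minimum run 10): every residue covered by a window
whose mean hydropathy reaches the cutoff is a candidate, and maximal candidate
runs shorter than 10 residues are discarded. This is a coarse
membrane-vs-cytosolic discriminator; it does not reproduce the helix counts
of dedicated topology predictors, and nothing downstream depends on exact
counts.

## Reference-anchored ortholog clustering

Candidate proteins (≥1 domain hit, plus proteins matching a non-enzymatic
reference entry such as the c-di-GMP effector regulator BldD, which joins by
identity alone) are assigned to the reference protein with the highest
semiglobal identity, provided identity ≥ 45% (`id_cutoff = 0.45`) and
coverage ≥ 60% of the reference. Ties break by coverage, then name. The 60%
coverage floor is this package's choice: it prevents a single shared domain
from promoting a fragment to full-protein orthology.

Assignments at ≤50% identity (`borderline_cutoff`) are re-validated as
bidirectional best hits (BBH) between the species' candidate set and the
reference set; failures are demoted and fall through to de novo clustering.
Unassigned candidates are clustered by single linkage at the same 45% cutoff,
with deterministic ids `NOVEL-001…` ordered by (size desc, smallest member)
and a majority-vote consensus architecture label.

Presence/absence is binary per species × cluster (paralogs collapse to
presence; per-protein evidence is retained in the JSON output). Conservation
categories follow the count of carrying species *n_c* out of *n*:
*core* (*n_c = n*), *soft core* (⌊0.95 n⌋ ≤ *n_c* < *n*), *unique*
(*n_c* = 1), *accessory* (otherwise). At *n* = 93 the bands are exactly
93 / 88–92 / 2–87 / 1; the 0.95 fraction generalizes the same bands to any
*n* (at *n* = 20 the soft-core band is the single count 19).

## Synteny profiles

For an anchor cluster, the profile records the BBH identity of each of the
±k (default 3) genes flanking the anchor in the reference genome, evaluated
against a target genome. The BBH is computed against the target's full
proteome, but a partner only scores if it lies within k+2 gene ranks of the
target's own anchor copy — otherwise a translocated homolog would count as
conserved context. A flank whose partner is absent or rejected scores 0;
slots beyond the replicon edge are missing (NaN), deliberately distinct from
0 ("no data" vs "context lost"). Offset 0 carries the anchor's own assignment
identity, so the row of the reference species itself is 100 everywhere.
Neighborhoods are strand- and distance-agnostic: pure gene-rank offsets.

## Expression normalization

The probe-level pipeline is: log2 → quantile normalization over the whole
matrix → per-probeset Tukey median polish; a probeset's expression on an
array is the fitted overall plus that array's column effect, and per-gene
developmental profiles are arithmetic means over biological replicates at
each time point. Conventions: quantile-normalization ties within a column
receive the mean of the reference values at their tied ranks; the polish
runs row sweep then column sweep, re-centering effects by their medians (the
textbook algorithm), stopping when the total absolute residual changes by
less than `tol = 0.01` or after `max_iter = 10` iterations; the
decomposition reconstructs its input exactly at every iteration; a
single-probe probeset degenerates to its normalized probe row. Convolution
background correction (the first step of full RMA) is intentionally absent.

Quantile normalization is a distribution-level transform: it is exact at
removing array-wide technical shifts but distorts genuine per-gene signal in
proportion to how much of the matrix carries signal. The recovery tests
therefore measure what the pipeline can honestly deliver — see below.

## Synthetic data: what it emulates, and what it does not

The pan-genome generator plants protein families (diverged copies of the
reference proteins at controlled identities, substitutions never touching
annotated functional residues unless a degenerate motif is explicitly
planted), per-species losses (Bernoulli or deterministically planted),
conserved flank-gene neighborhoods around each anchor (with optional
rearrangements), and unrelated decoy genes, emitting standard GenBank flat
files plus a truth table. Random scaffolds are post-processed so that no
window outside a planted TM block reaches the TM threshold, as expected of
real soluble regions. It does not model codon usage, GC content, operon
structure, or phylogenetic correlation among species — so passing recovery
tests demonstrates correctness of the clustering logic under controlled
divergence, not robustness to genome-annotation noise.

The standard recovery benchmark (`recovery_benchmark_spec`) uses 20 species,
the ten enzyme families at identities spread over 0.60–0.80 with 10% loss,
one family with a single planted loss (expected soft core at n = 20), and a
decoy family at 35% identity that must never be assigned to a reference
cluster. These sizes keep the benchmark in the half-minute range while
leaving a wide margin to the 45% cutoff on both sides.

The expression generator emulates a replicated 7-point developmental time
course (8–20 h): log2 intensity = probeset baseline (uniform 6–10) + probe
effect (sd 0.5) + array effect + Gaussian noise (default sd 0.1). Only 20%
of probesets carry developmental array effects (per-time-point, sd 1.0,
shared by replicates, centered over the time course); the rest are flat.
This majority-unchanged design is the regime in which between-array quantile
normalization is statistically appropriate; with all genes responding, no
distribution-matching normalization can recover effects faithfully. Recovery
is scored as the mean absolute deviation of recovered from planted
array-effect differences; at the default density (200 probesets × 11 probes)
it is ≈0.04 log2, and the polish step alone is exact on additive matrices.

## Synthetic reference fixtures

No real sequence data ships with the package. The exemplar domains and the
reference protein set (ten chromosomal turnover proteins, one plasmid-encoded
GGDEF protein, and the non-enzymatic regulator BldD) are generated
deterministically from fixed seeds and stored under `src/panscan/data/` with
`.synthetic` in every filename. The set mirrors the canonical inventory of a
*S. venezuelae*-like model organism in structure: four GGDEF-only proteins,
five GGDEF+EAL composites (one with a degenerate EAL, one bifunctional
candidate, two PDEs whose GGDEF A-site is atypical), two HD-GYP proteins
(one degenerate), with 10TM/6TM membrane anchors where appropriate. Each
protein's domain copy is diverged to 70% identity from the exemplar (functional
residues pinned), which keeps inter-reference identities well below the 45%
ortholog cutoff (measured maximum ≈38%) while keeping every domain far above
the 30% detection floor. A drift-guard test asserts the shipped files equal
the builder's output.

## Numerical and degenerate-input conventions

* Alignment mode, thresholds and tie-breaks are fixed as above; every seeded
  generator is a pure function of (spec, seed).
* An A-site not covered by the domain alignment grades degenerate with an
  all-`X` motif (logged, no exception).
* BBH requires a *unique* best hit in both directions; score ties disqualify.
* `classify_conservation` rejects counts outside [1, n].
* Quantile normalization rejects missing cells; the polish accepts any
  matrix with at least one row and column.
* Genome ingestion keeps replicons of unknown kind (only explicit plasmids
  are excluded), converts coordinates 1-based→0-based half-open at a single
  point, and uses minimal-start/maximal-end ordering for compound locations.

## Known limitations

* Sensory domains (PAS/GAF) are not detected; they never drive an activity
  call, but architecture strings therefore omit them.
* No profile-HMM scanning: detection power against very remote domains
  (<~30% identity to the exemplar) is limited by pairwise alignment.
* The genus-scale claims of a real 93-genome survey require the actual
  genome set; this package reproduces the analysis machinery and validates
  it on synthetic pan-genomes only.
* TM segment counts are heuristic (see above).
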