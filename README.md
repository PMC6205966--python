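# panscan

Pan-genome analysis of bacterial **c-di-GMP turnover proteins**: the GGDEF-domain
diguanylate cyclases (DGCs) that synthesize the second messenger
cyclic di-GMP, and the EAL/HD-GYP-domain phosphodiesterases (PDEs) that
degrade it. In *Streptomyces* and related Actinobacteria, c-di-GMP gates the
developmental switch from vegetative growth to sporulation, so the inventory
and conservation of these enzymes across a genus is of direct biological
interest.

`panscan` is for comparative genomicists who want, from a set of annotated
genomes (GenBank flat files) and a reference proteome, a reproducible
answer to four questions:

1. **What turnover enzymes does each genome encode?** Domains are located by
   pairwise alignment against exemplar GGDEF/EAL/HD-GYP sequences
   (BLOSUM62, gap 10/0.5), active-site residues are read through the
   alignment column map, and each protein is classified:
   intact `GG[D/E]EF` A-site ⇒ DGC; intact `E-x-L` motif + catalytic
   glutamate ⇒ PDE; intact H…D dyad + GYP ⇒ PDE; both A-sites intact ⇒
   bifunctional DGC/PDE candidate; recognizable domains with eroded active
   sites ⇒ degenerate. Transmembrane segments come from a Kyte–Doolittle
   sliding window (19 residues, cutoff 1.6).
2. **Which proteins are orthologs?** Reference-anchored assignment at ≥45%
   semiglobal identity and ≥60% reference coverage; borderline calls (≤50%)
   are validated as bidirectional best hits (BBH); leftovers cluster de novo
   by single linkage at the same cutoff.
3. **How conserved is each cluster?** Binary presence/absence per species
   with categories *core* (all *n* species), *soft core*
   (⌊0.95 *n*⌋ … *n*−1; at *n* = 93 that is 88–92), *accessory*, *unique*.
4. **Is the genomic context conserved?** Per anchor gene, the BBH identity
   of the ±3 flanking genes against each target genome, as heatmap-ready
   matrices (0 = flank lost/rearranged, missing = replicon edge).

A fifth, independent stage normalizes developmental microarray time courses
the way RMA summarizes probes: log2 → quantile normalization → per-probeset
Tukey median polish → mean log2 profiles over biological replicates.

Everything runs with no network and no external databases: the package ships
deterministic **synthetic** reference fixtures (see
`src/panscan/data/*.synthetic.*`) and a seeded simulator that emits GenBank
pan-genomes and probe matrices with known truth tables, so the whole pipeline
is testable end to end.

## Worked example

Annotate a proteome (here the packaged reference set itself, exported to
FASTA):

```sh
$ panscan annotate --genome demo.faa --fasta
locus_tag  architecture       protein_class           activity  asite_motifs         tm_count
cdgA       GGDEF-EAL          DGC                     DGC       GGDEF:GGDEF;EAL:EVL  0
cdgB       GGDEF              DGC                     DGC       GGDEF:GGDEF          0
cdgC       10TM-GGDEF-degEAL  DGC                     DGC       GGDEF:GGDEF;EAL:QVD  10
cdgD       GGDEF              DGC                     DGC       GGDEF:GGDEF          0
cdgE       GGDEF              DGC                     DGC       GGDEF:GGDEF          0
cdgF       10TM-GGDEF-EAL     bifunctional_candidate  DGC/PDE   GGDEF:GGDEF;EAL:EVL  10
rmdA       GGDEF-EAL          PDE                     PDE       GGDEF:GGDQF;EAL:EVL  0
rmdB       6TM-GGDEF-EAL      PDE                     PDE       GGDEF:GGDQF;EAL:EVL  6
hdgA       6TM-HD-GYP         PDE                     PDE       HD-GYP:GYP           6
hdgB       6TM-degHD-GYP      degenerate              none      HD-GYP:ASR           6
pcdgG      GGDEF              DGC                     DGC       GGDEF:GGDEF          0
```

Reading one row: `cdgC` is a membrane protein (10 predicted TM helices) with
an intact GGDEF A-site (`GGDEF`) and a degenerate EAL domain (motif `QVD`
instead of `E-x-L`), hence an active DGC despite carrying both domains.

Run the full pipeline on a simulated 4-species pan-genome from a YAML config
(`simulate: {n_species: 4}`, `seed: 7`):

```sh
$ panscan run --config demo.yaml
{
 "stages": {
  "pangenome": {
   "category_tallies": {"core": 6, "soft_core": 5},
   "clusters_per_species": {"max": 11, "min": 6, "mode": 11},
   "n_clusters": 11,
   "n_species": 4,
   "per_species_counts": {"SP001": 11, "SP002": 6, "SP003": 11, "SP004": 11}
  }
 }
}
```

Eleven clusters were recovered; six are present in all four species (core),
five missed one species (soft core — at *n* = 4 the band is the single count
3); species SP002 lost five genes to the simulator's 10% loss process. The
output directory additionally contains `annotations.tsv`,
`presence_absence.tsv` (0/1 species × cluster), `categories.tsv`,
`assignments.json` (per-assignment evidence) and, when enabled,
`synteny_<anchor>.tsv` and `profiles.tsv`.

Other entry points: `panscan cluster --genomes DIR`, `panscan synteny
--genomes DIR --anchors bldD,cdgB,cdgC,rmdA,rmdB -k 3`, `panscan expression
--matrix M.tsv --map P.tsv --design D.tsv`, and `panscan simulate
pangenome|expression` to generate seeded synthetic inputs with truth tables.

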