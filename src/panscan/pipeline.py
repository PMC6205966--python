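"""End-to-end orchestration: annotate, cluster, synteny, expression, report.

``run_pangenome_analysis`` is the library entry point used both by the CLI
and by the test surface: it scans every protein of every genome for
GGDEF/EAL/HD-GYP domains, grades active sites, assigns candidates to
reference-anchored ortholog clusters (with BBH validation of borderline
identities), clusters the leftovers de novo, and derives the binary
presence/absence matrix with conservation categories.  Proteins matching a
non-enzymatic reference entry (the c-di-GMP effector regulator) join the
analysis through identity alone, since they carry no turnover domain.

``run_pipeline`` wraps the stages behind a single config with fail-fast
validation and fixed output filenames (presence_absence.tsv,
categories.tsv, annotations.tsv, synteny_<anchor>.tsv, profiles.tsv,
summary.json).
"""

from __future__ import annotations

import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import expression as expr_mod
from .domain_annotation import annotate_protein, load_reference_domains, scan_domains
from .genome_io import Genome, read_genbank
from .pangenome import (
    OrthologAssignment,
    PangenomeConfig,
    PresenceAbsenceMatrix,
    assign_ortholog,
    build_presence_absence,
    classify_conservation,
    cluster_unassigned,
    validate_borderline,
)
from .references import CHROMOSOMAL_ORDER, reference_protein_set
from .synteny import flanking_identity_profile, synteny_heatmap_matrix

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    annotations: pd.DataFrame  # per-protein evidence for candidate proteins
    assignments: list[OrthologAssignment]
    novel_clusters: dict[str, dict]
    matrix: PresenceAbsenceMatrix
    categories: pd.DataFrame  # cluster, count, category


def run_pangenome_analysis(
    genomes: list[Genome],
    cfg: PangenomeConfig = PangenomeConfig(),
    reference_set: dict[str, str] | None = None,
    min_identity: float = 30.0,
    min_coverage: float = 60.0,
) -> AnalysisResult:
    """Full reference-anchored ortholog analysis over a set of genomes."""
    domains = load_reference_domains()
    if reference_set is None:
        reference_set = reference_protein_set()
    # reference entries that carry no turnover domain (e.g. the effector
    # regulator) are matched by identity over all proteins, not by domain scan
    non_enzyme_refs = {
        name: seq for name, seq in reference_set.items()
        if not scan_domains(seq, domains, min_identity, min_coverage)
    }

    ann_rows = []
    assignments: list[OrthologAssignment] = []
    candidate_sets: dict[str, dict[str, str]] = {}
    unassigned: dict[tuple[str, str], str] = {}
    architectures: dict[tuple[str, str], str] = {}

    for genome in genomes:
        sp = genome.species_id
        candidate_sets[sp] = {}
        for gene in genome.genes():
            hits, sites, tm, call = annotate_protein(
                gene.protein, domains, min_identity, min_coverage
            )
            if hits:
                candidate_sets[sp][gene.locus_tag] = gene.protein
                ann_rows.append({
                    "species_id": sp,
                    "locus_tag": gene.locus_tag,
                    "architecture": call.architecture_string,
                    "protein_class": call.protein_class,
                    "activity": call.activity_label,
                    "asite_motifs": ";".join(
                        f"{s.domain}:{s.asite_motif}" for s in sites
                    ),
                    "tm_count": tm.count,
                })
                hit = assign_ortholog(gene.protein, reference_set, cfg)
            else:
                hit = (
                    assign_ortholog(gene.protein, non_enzyme_refs, cfg)
                    if non_enzyme_refs else None
                )
                if hit is not None:
                    candidate_sets[sp][gene.locus_tag] = gene.protein
            if hit is not None:
                name, idp, cov = hit
                assignments.append(
                    OrthologAssignment(
                        species_id=sp, locus_tag=gene.locus_tag,
                        cluster_name=name, identity_pct=idp, coverage_pct=cov,
                        validated=False, method="reference_anchor",
                    )
                )
            elif hits:
                unassigned[(sp, gene.locus_tag)] = gene.protein
                architectures[(sp, gene.locus_tag)] = call.architecture_string

    assignments = validate_borderline(assignments, reference_set,
                                      candidate_sets, cfg)
    kept = {(a.species_id, a.locus_tag) for a in assignments}
    for key, seq in list(unassigned.items()):
        if key in kept:
            del unassigned[key]
    # demoted borderline candidates also fall through to de novo clustering
    for sp, cands in candidate_sets.items():
        for tag, seq in cands.items():
            key = (sp, tag)
            if key not in kept and key not in unassigned and key in architectures:
                unassigned[key] = seq

    novel = cluster_unassigned(unassigned, cfg, architectures)
    for cid, info in novel.items():
        for sp, tag in info["members"]:
            assignments.append(
                OrthologAssignment(
                    species_id=sp, locus_tag=tag, cluster_name=cid,
                    identity_pct=float("nan"), coverage_pct=float("nan"),
                    validated=True, method="novel_linkage",
                )
            )

    species = [g.species_id for g in genomes]
    ref_order = [n for n in reference_set]
    ordered_refs = [n for n in CHROMOSOMAL_ORDER if n in ref_order] + [
        n for n in ref_order if n not in CHROMOSOMAL_ORDER
    ]
    matrix = build_presence_absence(assignments, novel, species, ordered_refs)
    n_species = len(species)
    cat_rows = []
    for cluster, count in matrix.counts.items():
        if count == 0:
            continue
        cat = classify_conservation(count, n_species, cfg, cluster_name=cluster)
        cat_rows.append({"cluster": cluster, "count": cat.count,
                         "category": cat.category})
    categories = pd.DataFrame(cat_rows)
    annotations = pd.DataFrame(ann_rows)
    return AnalysisResult(
        annotations=annotations,
        assignments=assignments,
        novel_clusters=novel,
        matrix=matrix,
        categories=categories,
    )


def summarize_matrix(matrix: PresenceAbsenceMatrix,
                     cfg: PangenomeConfig = PangenomeConfig()) -> dict:
    """Per-species cluster-count statistics and category tallies."""
    df = matrix.cells
    if df.empty:
        raise ValueError("empty presence/absence matrix")
    row_sums = df.sum(axis=1).astype(int)
    counts = Counter(row_sums.tolist())
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)
    n_species = len(df)
    tallies = Counter(
        classify_conservation(int(c), n_species, cfg).category
        for c in df.sum(axis=0)
        if c > 0
    )
    return {
        "n_species": n_species,
        "n_clusters": int((df.sum(axis=0) > 0).sum()),
        "clusters_per_species": {
            "min": int(row_sums.min()),
            "max": int(row_sums.max()),
            "mode": int(mode),
        },
        "per_species_counts": {sp: int(c) for sp, c in row_sums.items()},
        "category_tallies": dict(tallies),
    }


# ---------------------------------------------------------------------------
# config-driven pipeline

@dataclass
class PipelineConfig:
    genome_paths: list[str] = field(default_factory=list)
    simulate: dict | None = None  # kwargs for PanGenomeSimSpec
    exclude_plasmids: bool = True
    pangenome: PangenomeConfig = field(default_factory=PangenomeConfig)
    synteny_anchors: list[str] = field(default_factory=list)
    synteny_k: int = 3
    synteny_reference: str | None = None  # species id of the reference genome
    expression_matrix: str | None = None
    expression_probe_map: str | None = None
    expression_design: str | None = None
    out_dir: str = "panscan_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.genome_paths and self.simulate is None \
                and self.expression_matrix is None:
            raise ValueError("no stage enabled: provide genomes, a simulation "
                             "spec, or expression inputs")
        for p in self.genome_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        exp = [self.expression_matrix, self.expression_probe_map,
               self.expression_design]
        if any(exp) and not all(exp):
            raise ValueError("expression stage needs matrix, probe map and design")
        for p in exp:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def _load_expression_inputs(cfg: PipelineConfig) -> expr_mod.ProbeMatrix:
    intensities = pd.read_csv(cfg.expression_matrix, sep="\t", index_col=0)
    pm = pd.read_csv(cfg.expression_probe_map, sep="\t", index_col=0)
    probe_map = pm.iloc[:, 0].to_dict()
    ds = pd.read_csv(cfg.expression_design, sep="\t", index_col=0)
    design = {a: (float(r.iloc[0]), int(r.iloc[1])) for a, r in ds.iterrows()}
    return expr_mod.ProbeMatrix(intensities=intensities, probe_map=probe_map,
                                design=design)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written as
    summary.json).  Validation failures raise before any output is written."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    t0 = time.time()

    genomes: list[Genome] = []
    if cfg.simulate is not None:
        from .synthetic_data import PanGenomeSimSpec, SimFamily, default_families

        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        fams = sim.pop("families", None)
        if fams is None:
            families = default_families()
        else:
            families = tuple(
                f if isinstance(f, SimFamily) else SimFamily(**f) for f in fams
            )
        spec = PanGenomeSimSpec(families=families, **sim)
        from .synthetic_data import simulate_pangenome

        genomes, truth = simulate_pangenome(spec)
        truth.presence.to_csv(out / "truth_presence.tsv", sep="\t")
    for path in cfg.genome_paths:
        genomes.append(read_genbank(path, exclude_plasmids=cfg.exclude_plasmids))

    if genomes:
        result = run_pangenome_analysis(genomes, cfg.pangenome)
        result.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        result.matrix.cells.astype(int).to_csv(out / "presence_absence.tsv", sep="\t")
        result.categories.to_csv(out / "categories.tsv", sep="\t", index=False)
        with open(out / "assignments.json", "w") as fh:
            json.dump(
                [a.__dict__ for a in result.assignments], fh, indent=1, default=str
            )
        summary["stages"]["pangenome"] = summarize_matrix(result.matrix,
                                                          cfg.pangenome)

        for anchor in cfg.synteny_anchors:
            ref_sp = cfg.synteny_reference or genomes[0].species_id
            ref_genome = next(g for g in genomes if g.species_id == ref_sp)
            profiles = [
                flanking_identity_profile(anchor, ref_genome, g,
                                          result.assignments, k=cfg.synteny_k)
                for g in genomes
            ]
            mat = synteny_heatmap_matrix(profiles)
            mat.to_csv(out / f"synteny_{anchor}.tsv", sep="\t",
                       float_format="%.1f")
            summary["stages"].setdefault("synteny", {})[anchor] = {
                "mean_identity": float(mat.stack().mean()),
            }

    if cfg.expression_matrix:
        pm = _load_expression_inputs(cfg)
        expr = expr_mod.summarize_probesets(pm)
        profiles = expr_mod.mean_replicate_profile(expr, pm.design)
        expr_mod.profiles_to_frame(profiles).to_csv(
            out / "profiles.tsv", sep="\t", float_format="%.4f"
        )
        summary["stages"]["expression"] = {
            "n_genes": len(profiles),
            "n_time_points": len(profiles[0].time_points) if profiles else 0,
        }

    summary["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
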