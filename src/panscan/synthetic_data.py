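"""Seeded synthetic pan-genomes and probe matrices with known truth tables.

The pan-genome generator emulates, at desk scale, the statistical structure
of a genus-wide set of annotated genomes: each species carries diverged
copies of a set of reference-anchored protein families (planted at
controlled identities, with per-species losses), each anchor sits inside a
conserved flank-gene neighborhood that can be perturbed by rearrangements,
and every genome carries unrelated decoy genes.  Substitutions never touch
a family's functional residues unless a degenerate motif is explicitly
planted, so activity truth stays independent of identity truth.

The expression generator emulates a replicated developmental time-course
probe matrix: per-probeset additive probe and array effects plus Gaussian
noise on the log2 scale.  Array effects are centered across probesets so
that the global array distributions stay comparable — the regime in which
quantile normalization is the appropriate between-array step.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ProbeMatrix
from .genome_io import GeneRecord, Genome, Replicon, write_genbank
from .seqsim import dehydrophobize, mutate_to_identity, rand_protein, tm_block

__all__ = [
    "SimFamily", "PanGenomeSimSpec", "TruthTable",
    "mutate_to_identity", "simulate_pangenome", "simulate_expression",
    "default_families",
]


@dataclass(frozen=True)
class SimFamily:
    """One planted protein family.

    ``protected_positions`` (0-based, on ``sequence``) are never substituted
    or hit by indels; ``planted_asite`` (if set) is written into
    ``asite_span`` of the family reference before divergence, so every
    member of the family carries the motif.
    """

    name: str
    sequence: str
    target_identity: float
    loss_prob: float = 0.0
    planted_asite: str | None = None
    planted_tm: int = 0
    asite_span: tuple[int, int] | None = None
    protected_positions: tuple[int, ...] = ()
    lost_in: tuple[int, ...] = ()  # deterministic losses (species indices)
    activity: str | None = None  # planted activity class, for the truth table

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must be in (0, 1]")
        if not 0 <= self.loss_prob < 1:
            raise ValueError("loss_prob must be in [0, 1)")
        if self.planted_asite is not None:
            if self.asite_span is None:
                raise ValueError("planted_asite needs asite_span")
            lo, hi = self.asite_span
            if hi - lo != len(self.planted_asite):
                raise ValueError("planted_asite length must match asite_span")


@dataclass(frozen=True)
class PanGenomeSimSpec:
    n_species: int
    families: tuple[SimFamily, ...]
    flank_genes_per_anchor: int = 3
    flank_identity: float = 0.75
    rearrangement_prob: float = 0.0
    indel_rate: float = 0.0
    decoys_per_species: int = 5
    include_reference: bool = False  # emit an undiverged reference species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if len({f.name for f in self.families}) != len(self.families):
            raise ValueError("duplicate family names")


@dataclass
class TruthTable:
    """Ground truth recorded while emitting the synthetic pan-genome."""

    presence: pd.DataFrame  # species x family booleans
    identities: dict[tuple[str, str], float] = field(default_factory=dict)
    activity: dict[str, str | None] = field(default_factory=dict)
    rearrangements: list[tuple[str, str, int]] = field(default_factory=list)
    anchor_locus: dict[tuple[str, str], str] = field(default_factory=dict)


def default_families(
    identity: float = 0.7,
    loss_prob: float = 0.1,
    names: tuple[str, ...] | None = None,
) -> tuple[SimFamily, ...]:
    """Families derived from the packaged reference proteins: every member
    diverges to ``identity`` with all functional residues pinned."""
    from .references import CHROMOSOMAL_ORDER, load_reference_proteins

    prots = load_reference_proteins()
    fams = []
    for name in names or CHROMOSOMAL_ORDER:
        p = prots[name]
        protected = tuple(sorted({q for d in p.domains for q in d.protected}))
        fams.append(
            SimFamily(
                name=name,
                sequence=p.sequence,
                target_identity=identity,
                loss_prob=loss_prob,
                protected_positions=protected,
                activity=p.expected_class,
            )
        )
    return tuple(fams)


def _family_reference(fam: SimFamily, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """Apply planted motif / TM block to the family reference once."""
    seq = list(fam.sequence)
    protected = set(fam.protected_positions)
    if fam.planted_asite is not None:
        lo, hi = fam.asite_span
        seq[lo:hi] = fam.planted_asite
        protected |= set(range(lo, hi))
    seq = "".join(seq)
    if fam.planted_tm > 0:
        block = tm_block(fam.planted_tm, rng)
        protected = {p + len(block) for p in protected} | set(range(len(block)))
        seq = block + seq
    return seq, tuple(sorted(protected))


def simulate_pangenome(
    spec: PanGenomeSimSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[Genome], TruthTable]:
    """Emit one genome per species plus the truth table.

    Species are named SP001..SPnnn (plus REF000 when
    ``spec.include_reference``); each genome is a single chromosome whose
    gene order is: per family, the upstream flank genes, the anchor (when
    present), the downstream flank genes; then the decoy genes.  When
    ``out_dir`` is given the genomes are also written as GenBank flat files
    (<species>.gbk), byte-identical for equal (spec, seed).
    """
    ss = np.random.SeedSequence(spec.seed)

    # family-level constants: planted reference sequence and flank references
    fam_refs: dict[str, tuple[str, tuple[int, ...]]] = {}
    flank_refs: dict[str, list[str]] = {}
    kf = spec.flank_genes_per_anchor
    for fam in spec.families:
        fam_rng = np.random.default_rng(ss.spawn(1)[0])
        fam_refs[fam.name] = _family_reference(fam, fam_rng)
        flank_refs[fam.name] = [
            dehydrophobize(rand_protein(250, fam_rng), fam_rng)
            for _ in range(2 * kf)
        ]

    species_ids = [f"SP{i + 1:03d}" for i in range(spec.n_species)]
    if spec.include_reference:
        species_ids = ["REF000"] + species_ids

    presence = pd.DataFrame(
        False, index=species_ids, columns=[f.name for f in spec.families]
    )
    truth = TruthTable(presence=presence)
    truth.activity = {f.name: f.activity for f in spec.families}

    genomes: list[Genome] = []
    for sp_idx, sp in enumerate(species_ids):
        rng = np.random.default_rng(ss.spawn(1)[0])
        is_ref = sp == "REF000"
        idx_for_loss = sp_idx - (1 if spec.include_reference else 0)
        proteins: list[tuple[str, str]] = []  # (role, sequence)
        for fam in spec.families:
            ref_seq, protected = fam_refs[fam.name]
            if is_ref:
                present = True
            elif idx_for_loss in fam.lost_in:
                present = False
            else:
                present = rng.random() >= fam.loss_prob
            ident = 1.0 if is_ref else fam.target_identity
            flank_ident = 1.0 if is_ref else spec.flank_identity
            for j in range(kf):  # upstream flanks, outermost first
                proteins.append(
                    (f"{fam.name}:flank{j - kf}",
                     _flank(flank_refs[fam.name][j], flank_ident, spec, rng,
                            truth, sp, fam.name, j - kf, is_ref))
                )
            if present:
                seed = int(rng.integers(2**31 - 1))
                member = mutate_to_identity(
                    ref_seq, ident, 0.0 if is_ref else spec.indel_rate,
                    seed, protected,
                )
                proteins.append((f"{fam.name}:anchor", member))
                truth.presence.loc[sp, fam.name] = True
                truth.identities[(sp, fam.name)] = ident
            for j in range(kf):  # downstream flanks
                proteins.append(
                    (f"{fam.name}:flank{j + 1}",
                     _flank(flank_refs[fam.name][kf + j], flank_ident, spec,
                            rng, truth, sp, fam.name, j + 1, is_ref))
                )
        for _ in range(spec.decoys_per_species):
            proteins.append(("decoy", dehydrophobize(rand_protein(300, rng), rng)))

        genes = []
        pos = 200
        for i, (role, seq) in enumerate(proteins):
            tag = f"{sp}_{(i + 1) * 5:05d}"
            length = 3 * len(seq) + 3
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    product=role,
                    start=pos,
                    end=pos + length,
                    strand=1,
                    replicon_id=f"chr_{sp}",
                    replicon_kind="chromosome",
                    order_index=i,
                    protein=seq,
                )
            )
            if role.endswith(":anchor"):
                truth.anchor_locus[(sp, role.split(":")[0])] = tag
            pos += length + 150
        genomes.append(
            Genome(
                species_id=sp,
                replicons=[Replicon(replicon_id=f"chr_{sp}", kind="chromosome",
                                    genes=genes)],
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for g in genomes:
            write_genbank(g, out_dir / f"{g.species_id}.gbk")
    return genomes, truth


def _flank(ref: str, identity: float, spec: PanGenomeSimSpec,
           rng: np.random.Generator, truth: TruthTable, sp: str,
           fam_name: str, offset: int, is_ref: bool) -> str:
    if not is_ref and rng.random() < spec.rearrangement_prob:
        truth.rearrangements.append((sp, fam_name, offset))
        return dehydrophobize(rand_protein(len(ref), rng), rng)
    seed = int(rng.integers(2**31 - 1))
    return mutate_to_identity(ref, identity, spec.indel_rate, seed)


def recovery_benchmark_spec(seed: int = 42, n_species: int = 20) -> PanGenomeSimSpec:
    """The standard pan-genome recovery benchmark.

    Ten enzyme families planted at identities spread over 0.60-0.80 with 10%
    random per-species loss; one family (cdgE) instead carries a single
    deterministic loss (so its expected category is soft core at n = 20);
    and one decoy family diverged to 35% identity from the cdgF reference,
    which sits below the 45% ortholog cutoff and must never be assigned to a
    reference cluster.
    """
    from .references import CHROMOSOMAL_ORDER, load_reference_proteins

    prots = load_reference_proteins()
    enzymes = [n for n in CHROMOSOMAL_ORDER if n != "bldD"]
    identities = np.linspace(0.60, 0.80, len(enzymes))
    fams = []
    for name, ident in zip(enzymes, identities):
        p = prots[name]
        protected = tuple(sorted({q for d in p.domains for q in d.protected}))
        single_loss = name == "cdgE"
        fams.append(
            SimFamily(
                name=name,
                sequence=p.sequence,
                target_identity=float(round(ident, 3)),
                loss_prob=0.0 if single_loss else 0.1,
                lost_in=(n_species // 2,) if single_loss else (),
                protected_positions=protected,
                activity=p.expected_class,
            )
        )
    decoy_src = prots["cdgF"]
    fams.append(
        SimFamily(
            name="DECOY35",
            sequence=decoy_src.sequence,
            target_identity=0.35,
            loss_prob=0.0,
            protected_positions=tuple(
                sorted({q for d in decoy_src.domains for q in d.protected})
            ),
        )
    )
    return PanGenomeSimSpec(
        n_species=n_species,
        families=tuple(fams),
        decoys_per_species=3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    n_probesets: int = 200,
    probes_per_set: int = 11,
    time_points: tuple[float, ...] = (8, 10, 12, 14, 16, 18, 20),
    replicates: int = 2,
    effect_sd: float = 1.0,
    frac_de: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Probe matrix of a replicated time course with additive truth.

    log2 intensity = overall(probeset) + probe effect + array effect +
    N(0, noise_sd).  A fraction ``frac_de`` of probesets carry a
    developmental signal (per-time-point array effects, shared by
    replicates, centered over the time course); the rest are flat — the
    majority-unchanged regime in which between-array quantile normalization
    is the appropriate step.  Returns the matrix and the probeset x array
    truth table of planted array effects.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    arrays = [f"T{t:g}_r{r + 1}" for t in time_points for r in range(replicates)]
    genes = [f"G{i + 1:03d}" for i in range(n_probesets)]

    de = rng.random(n_probesets) < frac_de
    per_time = rng.normal(0.0, effect_sd, size=(n_probesets, len(time_points)))
    per_time[~de] = 0.0
    if de.any():
        per_time[de] -= per_time[de].mean(axis=1, keepdims=True)
    effects = np.repeat(per_time, replicates, axis=1)
    truth = pd.DataFrame(effects, index=genes, columns=arrays)

    overall = rng.uniform(6.0, 10.0, size=n_probesets)
    rows = []
    probe_ids = []
    probe_map = {}
    for gi, gene in enumerate(genes):
        probe_eff = rng.normal(0.0, 0.5, size=probes_per_set)
        probe_eff -= np.median(probe_eff)
        noise = rng.normal(0.0, noise_sd, size=(probes_per_set, len(arrays)))
        log2 = overall[gi] + probe_eff[:, None] + effects[gi][None, :] + noise
        rows.append(2.0 ** log2)
        for pj in range(probes_per_set):
            pid = f"{gene}_p{pj + 1:02d}"
            probe_ids.append(pid)
            probe_map[pid] = gene
    intensities = pd.DataFrame(
        np.vstack(rows), index=probe_ids, columns=arrays
    )
    design = {
        f"T{t:g}_r{r + 1}": (float(t), r + 1)
        for t in time_points for r in range(replicates)
    }
    return ProbeMatrix(intensities=intensities, probe_map=probe_map,
                       design=design), truth
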