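"""Conservation of the genomic context around anchor genes.

For an anchor ortholog (e.g. a widely conserved diguanylate-cyclase gene)
the profile records, for each of the k genes upstream and downstream of the
anchor in the reference genome, the percent identity of its bidirectional
best hit (BBH) in a target genome — but a BBH partner only counts if it
lies near the target's own anchor copy (within k+2 gene ranks), so that a
homolog translocated elsewhere in the genome does not score as conserved
context.  A flank whose partner is absent or rejected scores 0; slots
beyond the replicon edge are missing (NaN), which is distinct from 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import align_pair, score_pair
from .genome_io import Genome, neighborhood

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyProfile:
    anchor: str
    species_id: str
    k: int
    values: tuple[float, ...]  # 2k+1 identities; NaN = missing

    def __post_init__(self) -> None:
        if len(self.values) != 2 * self.k + 1:
            raise ValueError("profile must have 2k+1 slots")


def _best_hit(seq: str, proteome: dict[str, str]) -> str | None:
    best, best_s, tied = None, None, False
    for tag in sorted(proteome):
        s = score_pair(seq, proteome[tag], mode="local")
        if best_s is None or s > best_s:
            best, best_s, tied = tag, s, False
        elif s == best_s:
            tied = True
    return None if tied else best


def flanking_identity_profile(
    anchor_cluster: str,
    reference_genome: Genome,
    target_genome: Genome,
    assignments,
    k: int = 3,
) -> SyntenyProfile:
    """BBH identity of the ±k reference flanking genes within the target.

    ``assignments`` is an iterable of
    :class:`~panscan.pangenome.OrthologAssignment`; it must locate the
    anchor cluster in the reference genome, and should locate it in the
    target (otherwise the profile is all-missing).  Offset 0 carries the
    target anchor's own assignment identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_species: dict[str, dict[str, object]] = {}
    for a in assignments:
        if a.cluster_name == anchor_cluster:
            by_species.setdefault(a.species_id, {})[a.locus_tag] = a

    ref_anchors = by_species.get(reference_genome.species_id, {})
    if not ref_anchors:
        raise ValueError(
            f"anchor {anchor_cluster!r} not assigned in reference genome"
        )
    ref_anchor_tag = sorted(ref_anchors)[0]
    tgt_anchors = by_species.get(target_genome.species_id, {})
    nan = float("nan")
    if not tgt_anchors:
        logger.info(
            "anchor %s absent from %s: all-missing profile",
            anchor_cluster, target_genome.species_id,
        )
        return SyntenyProfile(
            anchor=anchor_cluster,
            species_id=target_genome.species_id,
            k=k,
            values=tuple([nan] * (2 * k + 1)),
        )
    tgt_anchor_tag = sorted(tgt_anchors)[0]

    tgt_rep, tgt_anchor = target_genome.find(tgt_anchor_tag)
    tgt_proteome = {g.locus_tag: g.protein for g in target_genome.genes()}
    ref_proteome = {g.locus_tag: g.protein for g in reference_genome.genes()}
    tgt_rank = {g.locus_tag: g.order_index for g in tgt_rep.genes}

    values = []
    for off, gene in neighborhood(reference_genome, ref_anchor_tag, k):
        if gene is None:
            values.append(nan)
            continue
        if off == 0:
            values.append(float(tgt_anchors[tgt_anchor_tag].identity_pct))
            continue
        fwd = _best_hit(gene.protein, tgt_proteome)
        if fwd is None:
            values.append(0.0)
            continue
        back = _best_hit(tgt_proteome[fwd], ref_proteome)
        near = (
            fwd in tgt_rank
            and abs(tgt_rank[fwd] - tgt_anchor.order_index) <= k + 2
        )
        if back == gene.locus_tag and near:
            idp = align_pair(gene.protein, tgt_proteome[fwd],
                             mode="semiglobal").identity_pct
            values.append(idp)
        else:
            values.append(0.0)
    return SyntenyProfile(
        anchor=anchor_cluster,
        species_id=target_genome.species_id,
        k=k,
        values=tuple(values),
    )


def synteny_heatmap_matrix(profiles: list[SyntenyProfile]) -> pd.DataFrame:
    """Assemble profiles sharing one anchor into a species x offset matrix
    (rows alphabetical; NaN marks replicon-edge truncation, 0 a lost or
    rearranged flank)."""
    if not profiles:
        raise ValueError("no profiles")
    anchors = {p.anchor for p in profiles}
    if len(anchors) > 1:
        raise ValueError(f"mixed anchors: {sorted(anchors)}")
    ks = {p.k for p in profiles}
    if len(ks) > 1:
        raise ValueError("profiles have differing k")
    k = ks.pop()
    rows = {p.species_id: p.values for p in sorted(profiles, key=lambda p: p.species_id)}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(range(-k, k + 1)))
    return df


def plot_synteny_heatmap(matrix: pd.DataFrame, anchor: str, path: str) -> None:
    """Grayscale heatmap figure of a synteny matrix (missing cells hatched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(4, max(2, 0.25 * len(matrix))), constrained_layout=True
    )
    data = matrix.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("Greys").copy()
    cmap.set_bad("lightsteelblue")
    im = ax.imshow(masked, vmin=0, vmax=100, cmap=cmap, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    ax.set_xlabel("gene offset from anchor")
    ax.set_title(anchor)
    fig.colorbar(im, ax=ax, label="BBH identity %")
    fig.savefig(path, dpi=150)
    plt.close(fig)
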