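"""Reference-anchored ortholog clustering across a pan-genome.

Candidate proteins (those carrying at least one GGDEF/EAL/HD-GYP domain
hit, plus any non-enzyme reference entries such as the effector regulator)
are assigned to the reference protein they are most identical to, provided
the semiglobal identity reaches the cutoff (default 45%) and the alignment
covers at least 60% of the reference.  Borderline assignments (identity at
or below 50%) are re-validated as bidirectional best hits between the
species' candidate set and the reference set.  Candidates matching no
reference are clustered de novo by single linkage at the same identity
cutoff and reported as NOVEL-nnn clusters.

Presence/absence across species is binary (paralogs collapse to presence)
and clusters are classified by the number of carrying species: *core*
(all species), *soft core* (at least floor(0.95 n) but not all), *unique*
(exactly one) and *accessory* (everything between).  At n = 93 the soft-core
band is 88-92 species and the accessory band 2-87.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .align import align_pair, score_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PangenomeConfig:
    id_cutoff: float = 0.45
    borderline_cutoff: float = 0.50
    coverage_min: float = 60.0  # percent of reference length
    softcore_frac: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.id_cutoff <= self.borderline_cutoff <= 1:
            raise ValueError("need 0 < id_cutoff <= borderline_cutoff <= 1")


@dataclass(frozen=True)
class OrthologAssignment:
    species_id: str
    locus_tag: str
    cluster_name: str
    identity_pct: float
    coverage_pct: float
    validated: bool
    method: str  # reference_anchor | novel_linkage


@dataclass(frozen=True)
class ConservationCategory:
    cluster_name: str
    count: int
    category: str  # core | soft_core | accessory | unique


@dataclass
class PresenceAbsenceMatrix:
    """Species x cluster boolean table; rows alphabetical by species,
    columns reference clusters first, then novel clusters."""

    cells: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.cells.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def counts(self) -> dict[str, int]:
        return self.cells.sum(axis=0).astype(int).to_dict()


# ---------------------------------------------------------------------------

def assign_ortholog(
    protein: str,
    reference_set: dict[str, str],
    cfg: PangenomeConfig = PangenomeConfig(),
) -> tuple[str, float, float] | None:
    """Best reference anchor for one protein, or ``None`` below cutoff.

    Returns ``(reference_name, identity_pct, coverage_pct)``.  The best
    reference is chosen by identity; ties break by coverage, then by
    lexicographic reference name.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    best = None
    for name in sorted(reference_set):
        aln = align_pair(protein, reference_set[name], mode="semiglobal")
        if aln.identity_pct < 100.0 * cfg.id_cutoff:
            continue
        if aln.coverage_pct < cfg.coverage_min:
            continue
        key = (aln.identity_pct, aln.coverage_pct)
        if best is None or key > best[0]:
            best = (key, name, aln)
    if best is None:
        return None
    _, name, aln = best
    return name, aln.identity_pct, aln.coverage_pct


def bbh(proteomeA: dict[str, str], proteomeB: dict[str, str]
        ) -> set[tuple[str, str, float]]:
    """Bidirectional best hits between two proteomes.

    A pair ``(a, b)`` is included iff ``b`` is ``a``'s unique best hit in B
    by alignment score and vice versa; the attached identity is for
    reporting.  The relation is symmetric.
    """
    if not proteomeA or not proteomeB:
        raise ValueError("both proteomes must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for a, seqa in proteomeA.items():
        for b, seqb in proteomeB.items():
            scores[(a, b)] = score_pair(seqa, seqb, mode="local")

    def unique_best(items, get_score):
        best, best_s, tied = None, None, False
        for key in items:
            s = get_score(key)
            if best_s is None or s > best_s:
                best, best_s, tied = key, s, False
            elif s == best_s:
                tied = True
        return None if tied else best

    bestA = {a: unique_best(proteomeB, lambda b, a=a: scores[(a, b)])
             for a in proteomeA}
    bestB = {b: unique_best(proteomeA, lambda a, b=b: scores[(a, b)])
             for b in proteomeB}
    pairs = set()
    for a, b in bestA.items():
        if b is not None and bestB.get(b) == a:
            idp = align_pair(proteomeA[a], proteomeB[b], mode="semiglobal").identity_pct
            pairs.add((a, b, idp))
    return pairs


def validate_borderline(
    assignments: list[OrthologAssignment],
    reference_set: dict[str, str],
    candidate_sets: dict[str, dict[str, str]],
    cfg: PangenomeConfig = PangenomeConfig(),
) -> list[OrthologAssignment]:
    """Re-test assignments at or below the borderline identity (default 50%)
    as BBHs between the species' candidate set and the reference set.

    Assignments above the borderline are validated unconditionally;
    borderline assignments failing the BBH test are dropped (their proteins
    fall through to de novo clustering).
    """
    out: list[OrthologAssignment] = []
    bbh_cache: dict[str, set[tuple[str, str]]] = {}
    for a in assignments:
        if a.method != "reference_anchor":
            out.append(a)
            continue
        if a.identity_pct > 100.0 * cfg.borderline_cutoff:
            out.append(replace(a, validated=True))
            continue
        if a.species_id not in bbh_cache:
            pairs = bbh(candidate_sets[a.species_id], reference_set)
            bbh_cache[a.species_id] = {(x, y) for x, y, _ in pairs}
        if (a.locus_tag, a.cluster_name) in bbh_cache[a.species_id]:
            out.append(replace(a, validated=True))
        else:
            logger.info(
                "demoting borderline assignment %s/%s -> %s (%.1f%%): not a BBH",
                a.species_id, a.locus_tag, a.cluster_name, a.identity_pct,
            )
    return out


def cluster_unassigned(
    candidates: dict[tuple[str, str], str],
    cfg: PangenomeConfig = PangenomeConfig(),
    architectures: dict[tuple[str, str], str] | None = None,
) -> dict[str, dict]:
    """Single-linkage clusters of unassigned candidates at the identity
    cutoff.

    ``candidates`` maps ``(species_id, locus_tag)`` to sequence.  Returns
    ``{cluster_id: {"members": [(species, locus), ...], "architecture": str}}``
    with deterministic ids NOVEL-001... ordered by (size desc, lexicographic
    smallest member).
    """
    keys = sorted(candidates)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if find(a) == find(b):
                continue
            idp = align_pair(candidates[a], candidates[b], mode="semiglobal").identity_pct
            if idp >= 100.0 * cfg.id_cutoff:
                parent[find(a)] = find(b)

    groups: dict = {}
    for k in keys:
        groups.setdefault(find(k), []).append(k)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    out = {}
    for i, members in enumerate(ordered, start=1):
        archs = [architectures.get(m, "") for m in members] if architectures else []
        consensus = Counter(a for a in archs if a).most_common(1)
        out[f"NOVEL-{i:03d}"] = {
            "members": sorted(members),
            "architecture": consensus[0][0] if consensus else "",
        }
    return out


def build_presence_absence(
    assignments: list[OrthologAssignment],
    novel_clusters: dict[str, dict],
    species: list[str],
    reference_order: list[str],
) -> PresenceAbsenceMatrix:
    """Binary species x cluster table (paralogs collapse to presence).

    Species rows are alphabetical; columns are the reference clusters in
    ``reference_order`` followed by novel clusters in id order.  Clusters
    never observed in any species are dropped except reference clusters,
    which always keep their column.
    """
    rows = sorted(species)
    cols = list(reference_order) + sorted(novel_clusters)
    df = pd.DataFrame(False, index=rows, columns=cols)
    for a in assignments:
        if a.cluster_name in df.columns and a.species_id in df.index:
            df.loc[a.species_id, a.cluster_name] = True
    for cid, info in novel_clusters.items():
        for sp, _locus in info["members"]:
            if sp in df.index:
                df.loc[sp, cid] = True
    empty = [s for s in rows if not df.loc[s].any()]
    if empty:
        logger.info("species with zero candidate proteins: %s", empty)
    return PresenceAbsenceMatrix(cells=df)


def classify_conservation(
    count: int,
    n_species: int,
    cfg: PangenomeConfig = PangenomeConfig(),
    cluster_name: str = "",
) -> ConservationCategory:
    """Conservation category of a cluster present in ``count`` of
    ``n_species`` species.

    core iff count == n; soft_core iff floor(softcore_frac * n) <= count < n;
    unique iff count == 1; else accessory.  (Soft-core wins over unique in
    the degenerate tiny-n overlap; with the default 0.95 fraction the bands
    at n = 93 are 93 / 88-92 / 2-87 / 1.)
    """
    if not 1 <= count <= n_species:
        raise ValueError(f"count must be in [1, {n_species}]: {count}")
    soft_lo = int(cfg.softcore_frac * n_species)
    if count == n_species:
        cat = "core"
    elif count >= soft_lo:
        cat = "soft_core"
    elif count == 1:
        cat = "unique"
    else:
        cat = "accessory"
    return ConservationCategory(cluster_name=cluster_name, count=count, category=cat)
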