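"""GGDEF/EAL/HD-GYP domain detection, active-site grading and activity calls.

Domains are located by local alignment against packaged reference domain
sequences rather than by querying a remote domain database; the classical
COG identifiers for these families (COG2199 for GGDEF, COG2200 for EAL,
COG3437/COG2206 for HD-GYP, among others) are retained as metadata labels
on the reference entries.

Activity logic follows the genetics of c-di-GMP turnover enzymes:

* a GGDEF domain with an intact GG[D/E]EF A-site is a diguanylate cyclase
  (DGC); single-mismatch motifs such as GGDDF are graded *atypical* (no
  activity assigned), multiply substituted motifs such as ALLEF or AADEF
  are *degenerate*;
* an EAL domain is a phosphodiesterase (PDE) when its E-x-L motif is
  present, the second catalytic glutamate is conserved, and at least 75%
  of the listed catalytic positions are conserved;
* an HD-GYP domain is a PDE when both the H..D dyad and all three GYP
  residues are conserved; a domain missing any GYP residue is degenerate.

A protein with both an active GGDEF and an active EAL (or HD-GYP) domain is
reported as a bifunctional DGC/PDE candidate.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .align import AlignmentResult, align_pair

logger = logging.getLogger(__name__)

DOMAIN_KINDS = ("GGDEF", "EAL", "HD-GYP")


@dataclass(frozen=True)
class ReferenceDomain:
    """A reference domain sequence with annotated functional positions.

    Spans are 0-based half-open intervals on ``sequence``; positions are
    0-based.  ``dyad_positions`` is only set for HD-GYP (the H and D of the
    metal-binding dyad); ``key_glutamate`` only for EAL (the second
    catalytic glutamate).
    """

    name: str  # GGDEF | EAL | HD-GYP
    source_protein: str
    sequence: str
    asite_span: tuple[int, int]
    isite_span: tuple[int, int] | None
    catalytic_positions: tuple[int, ...]
    dyad_positions: tuple[int, int] | None = None
    key_glutamate: int | None = None
    cog: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.asite_span
        if not 0 <= lo < hi <= len(self.sequence):
            raise ValueError(f"{self.name}: asite_span out of bounds")
        if self.name == "GGDEF":
            motif = self.sequence[lo:hi]
            if not re.fullmatch(r"GG[DE]EF", motif):
                raise ValueError(f"GGDEF reference A-site is {motif!r}")

    @property
    def asite_motif(self) -> str:
        lo, hi = self.asite_span
        return self.sequence[lo:hi]


@dataclass(frozen=True)
class DomainHit:
    domain: str
    query_span: tuple[int, int]
    alignment: AlignmentResult
    reference: ReferenceDomain


@dataclass(frozen=True)
class ActiveSiteCall:
    domain: str
    asite_motif: str
    isite_motif: str | None
    catalytic_conserved: float
    grade: str  # intact | atypical | degenerate


@dataclass(frozen=True)
class TMAnnotation:
    segments: tuple[tuple[int, int], ...]
    count: int
    membrane_bound: bool


@dataclass(frozen=True)
class ActivityCall:
    per_domain: tuple[tuple[str, str], ...]  # (domain, {DGC,PDE,inactive})
    protein_class: str  # DGC | PDE | bifunctional_candidate | degenerate | none
    architecture_string: str

    @property
    def activity_label(self) -> str:
        """The enzymatic-activity column label: proteins whose domains are
        all inactive and proteins without domains both read 'none'."""
        return {
            "DGC": "DGC",
            "PDE": "PDE",
            "bifunctional_candidate": "DGC/PDE",
            "degenerate": "none",
            "none": "none",
        }[self.protein_class]


# ---------------------------------------------------------------------------
# packaged reference domains

def load_reference_domains() -> list[ReferenceDomain]:
    """Load the packaged (synthetic) reference domain set: one exemplar per
    domain kind with A-site/I-site spans and catalytic positions."""
    data = resources.files("panscan.data")
    meta = json.loads((data / "reference_domains.synthetic.json").read_text())
    seqs: dict[str, str] = {}
    name = None
    for line in (data / "reference_domains.synthetic.fasta").read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    refs = []
    for entry in meta["domains"]:
        refs.append(
            ReferenceDomain(
                name=entry["name"],
                source_protein=entry["source_protein"],
                sequence=seqs[entry["name"]],
                asite_span=tuple(entry["asite_span"]),
                isite_span=tuple(entry["isite_span"]) if entry.get("isite_span") else None,
                catalytic_positions=tuple(entry["catalytic_positions"]),
                dyad_positions=tuple(entry["dyad_positions"]) if entry.get("dyad_positions") else None,
                key_glutamate=entry.get("key_glutamate"),
                cog=entry.get("cog", ""),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# operations

def scan_domains(
    protein: str,
    refs: list[ReferenceDomain],
    min_identity: float = 30.0,
    min_coverage: float = 60.0,
) -> list[DomainHit]:
    """Locate domains by best local alignment against each reference.

    A reference yields a hit when its best local alignment passes both the
    identity and the coverage threshold.  Overlapping hits of the same
    domain kind are deduplicated keeping the highest score (ties: left-most
    query span).  Hits are returned in query-coordinate order.
    """
    if not refs:
        raise ValueError("empty reference domain list")
    hits: list[DomainHit] = []
    for ref in refs:
        aln = align_pair(protein, ref.sequence, mode="local")
        if aln.identity_pct >= min_identity and aln.coverage_pct >= min_coverage:
            hits.append(
                DomainHit(
                    domain=ref.name,
                    query_span=aln.query_span,
                    alignment=aln,
                    reference=ref,
                )
            )
    # dedupe same-kind overlaps, highest score first, left-most on ties
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.alignment.score, h.query_span[0])):
        clash = any(
            k.domain == hit.domain
            and k.query_span[0] < hit.query_span[1]
            and hit.query_span[0] < k.query_span[1]
            for k in kept
        )
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: h.query_span[0])
    return kept


def _mapped_motif(protein: str, column_map: dict[int, int | None],
                  span: tuple[int, int]) -> str:
    out = []
    for pos in range(span[0], span[1]):
        q = column_map.get(pos)
        out.append(protein[q] if q is not None else "X")
    return "".join(out)


def _conserved(protein: str, ref: ReferenceDomain,
               column_map: dict[int, int | None], positions) -> list[bool]:
    flags = []
    for pos in positions:
        q = column_map.get(pos)
        flags.append(q is not None and protein[q] == ref.sequence[pos])
    return flags


def extract_active_site(protein: str, hit: DomainHit) -> ActiveSiteCall:
    """Read the query residues aligned to the reference active-site columns
    and grade the site (intact / atypical / degenerate)."""
    protein = protein.upper()
    ref = hit.reference
    cmap = hit.alignment.column_map
    span_covered = all(pos in cmap for pos in range(*ref.asite_span))
    if not span_covered:
        logger.warning(
            "A-site span of %s not covered by alignment; grading degenerate",
            ref.name,
        )
        return ActiveSiteCall(
            domain=ref.name,
            asite_motif="X" * (ref.asite_span[1] - ref.asite_span[0]),
            isite_motif=None,
            catalytic_conserved=0.0,
            grade="degenerate",
        )

    asite = _mapped_motif(protein, cmap, ref.asite_span)
    isite = _mapped_motif(protein, cmap, ref.isite_span) if ref.isite_span else None
    cat = _conserved(protein, ref, cmap, ref.catalytic_positions)
    frac = float(np.mean(cat)) if cat else 1.0

    grade = _grade(protein, ref, cmap, asite, frac)
    return ActiveSiteCall(
        domain=ref.name,
        asite_motif=asite,
        isite_motif=isite,
        catalytic_conserved=frac,
        grade=grade,
    )


def _grade(protein: str, ref: ReferenceDomain, cmap, asite: str, frac: float) -> str:
    if ref.name == "GGDEF":
        # mismatches against the GG[D/E]EF consensus; 1 -> atypical (e.g.
        # GGDDF), >=2 -> degenerate (e.g. ALLEF, AADEF)
        consensus = ["G", "G", "DE", "E", "F"]
        mism = sum(1 for a, c in zip(asite, consensus) if a not in c)
        return "intact" if mism == 0 else ("atypical" if mism == 1 else "degenerate")
    if ref.name == "EAL":
        pattern_ok = len(asite) == 3 and asite[0] == "E" and asite[2] == "L"
        q = cmap.get(ref.key_glutamate) if ref.key_glutamate is not None else None
        key_ok = q is not None and protein[q] == "E"
        if pattern_ok and key_ok and frac >= 0.75:
            return "intact"
        if pattern_ok and key_ok:
            return "atypical"
        return "degenerate"
    if ref.name == "HD-GYP":
        gyp_ok = all(_conserved(protein, ref, cmap, range(*ref.asite_span)))
        dyad_ok = ref.dyad_positions is not None and all(
            _conserved(protein, ref, cmap, ref.dyad_positions)
        )
        if gyp_ok and dyad_ok:
            return "intact"
        if gyp_ok:
            return "atypical"
        return "degenerate"
    raise ValueError(f"unknown domain kind {ref.name!r}")


_ACTIVE_ROLE = {"GGDEF": "DGC", "EAL": "PDE", "HD-GYP": "PDE"}


def classify_activity(
    hits: list[DomainHit],
    sites: list[ActiveSiteCall],
    tm: TMAnnotation | None = None,
) -> ActivityCall:
    """Combine domain hits, active-site grades and membrane prediction into a
    per-protein enzymatic activity call and a canonical architecture string.

    GGDEF intact => DGC-active; EAL or HD-GYP intact => PDE-active; atypical
    and degenerate sites are inactive.  Both a DGC- and a PDE-active domain
    => bifunctional candidate; domains present but none active => degenerate;
    no domain hits => none.
    """
    if len(hits) != len(sites):
        raise ValueError("need exactly one ActiveSiteCall per DomainHit")
    order = sorted(range(len(hits)), key=lambda i: hits[i].query_span[0])
    per_domain = []
    parts = []
    for i in order:
        hit, site = hits[i], sites[i]
        active = site.grade == "intact"
        role = _ACTIVE_ROLE[hit.domain] if active else "inactive"
        per_domain.append((hit.domain, role))
        parts.append(("deg" if site.grade == "degenerate" else "") + hit.domain)

    roles = {r for _, r in per_domain}
    if not per_domain:
        protein_class = "none"
    elif "DGC" in roles and "PDE" in roles:
        protein_class = "bifunctional_candidate"
    elif "DGC" in roles:
        protein_class = "DGC"
    elif "PDE" in roles:
        protein_class = "PDE"
    else:
        protein_class = "degenerate"

    arch = "-".join(parts) if parts else "none"
    if tm is not None and tm.count >= 2:
        arch = f"{tm.count}TM-{arch}"
    return ActivityCall(
        per_domain=tuple(per_domain),
        protein_class=protein_class,
        architecture_string=arch,
    )


# ---------------------------------------------------------------------------
# transmembrane prediction (Kyte-Doolittle sliding window)

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def predict_tm(protein: str, window: int = 19, threshold: float = 1.6,
               min_run: int = 10) -> TMAnnotation:
    """Predict transmembrane segments with the classical Kyte-Doolittle
    sliding-window heuristic.

    All residues covered by a window whose mean hydropathy is >= ``threshold``
    become candidates; maximal candidate runs shorter than ``min_run`` are
    discarded.  This is a coarse membrane/cytosolic discriminator; exact
    helix counts from dedicated topology predictors are not reproduced.
    """
    protein = protein.upper()
    n = len(protein)
    if n < window:
        return TMAnnotation(segments=(), count=0, membrane_bound=False)
    vals = np.array([KYTE_DOOLITTLE[a] for a in protein])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    marked = np.zeros(n, dtype=bool)
    for i in np.nonzero(means >= threshold)[0]:
        marked[i : i + window] = True
    segments = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            if j - i >= min_run:
                segments.append((i, j))
            i = j
        else:
            i += 1
    return TMAnnotation(
        segments=tuple(segments),
        count=len(segments),
        membrane_bound=len(segments) >= 1,
    )


def annotate_protein(
    protein: str,
    refs: list[ReferenceDomain],
    min_identity: float = 30.0,
    min_coverage: float = 60.0,
) -> tuple[list[DomainHit], list[ActiveSiteCall], TMAnnotation, ActivityCall]:
    """Convenience wrapper: scan, grade, predict TM, classify."""
    hits = scan_domains(protein, refs, min_identity=min_identity,
                        min_coverage=min_coverage)
    sites = [extract_active_site(protein, h) for h in hits]
    tm = predict_tm(protein)
    call = classify_activity(hits, sites, tm)
    return hits, sites, tm, call
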