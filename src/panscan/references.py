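"""Synthetic reference fixtures: exemplar domains and reference proteins.

The package ships a fully synthetic reference set that mirrors the domain
inventory of the *Streptomyces venezuelae* c-di-GMP machinery in structure:
ten chromosomal turnover proteins (four GGDEF-only, four composite
GGDEF+EAL of which one carries a degenerate EAL, two HD-GYP of which one is
degenerate), one plasmid-encoded GGDEF protein, and the non-enzymatic
c-di-GMP effector regulator BldD.  The sequences themselves are generated
deterministically from fixed seeds (random scaffolds, hydrophobic TM
blocks, and diverged copies of three canonical exemplar domains with their
functional residues pinned), so no real genome data is required anywhere in
the test surface.  Filenames of the shipped fixtures carry the
``.synthetic`` marker.

Each reference protein records where its domains and functional residues
sit, which the pan-genome simulator uses to keep planted activity truth
independent of planted identity truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .domain_annotation import ReferenceDomain
from .seqsim import dehydrophobize, mutate_to_identity, rand_protein, tm_block

#: divergence of each protein's domain copy from the canonical exemplar;
#: keeps paralogous references well below the 45% ortholog cutoff while
#: keeping their domains comfortably detectable by the 30%-identity scan
DOMAIN_COPY_IDENTITY = 0.70

#: chromosomal reference clusters in presentation order (enzymes first,
#: then the non-enzyme effector BldD); the plasmid-encoded pcdgG is part of
#: the annotation fixtures but not of the ortholog reference set
CHROMOSOMAL_ORDER = (
    "cdgA", "cdgB", "cdgC", "cdgD", "cdgE", "cdgF",
    "rmdA", "rmdB", "hdgA", "hdgB", "bldD",
)
TABLE_ORDER = CHROMOSOMAL_ORDER[:-1] + ("pcdgG",)


# ---------------------------------------------------------------------------
# canonical exemplar domains

def build_reference_domains() -> list[ReferenceDomain]:
    """Construct the three canonical exemplar domains (deterministic)."""
    rng = np.random.default_rng(101)
    g = list(dehydrophobize(rand_protein(170, rng), rng))
    g[30], g[60], g[140] = "K", "R", "E"
    g[95:99] = "RKSD"  # I-site RxxD, ending 5 residues upstream of the A-site
    g[103:108] = "GGDEF"
    ggdef = ReferenceDomain(
        name="GGDEF",
        source_protein="synthetic exemplar (DGC)",
        sequence="".join(g),
        asite_span=(103, 108),
        isite_span=(95, 99),
        catalytic_positions=(30, 60, 103, 104, 105, 106, 107, 140),
        cog="COG2199",
    )

    rng = np.random.default_rng(102)
    e = list(dehydrophobize(rand_protein(180, rng), rng))
    e[8:11] = "EVL"
    e[70], e[95], e[120], e[150] = "E", "N", "E", "D"
    eal = ReferenceDomain(
        name="EAL",
        source_protein="synthetic exemplar (PDE)",
        sequence="".join(e),
        asite_span=(8, 11),
        isite_span=None,
        catalytic_positions=(8, 10, 70, 95, 120, 150),
        key_glutamate=70,
        cog="COG2200",
    )

    rng = np.random.default_rng(103)
    h = list(dehydrophobize(rand_protein(170, rng), rng))
    h[40], h[75] = "H", "D"
    h[120:123] = "GYP"
    hdgyp = ReferenceDomain(
        name="HD-GYP",
        source_protein="synthetic exemplar (PDE)",
        sequence="".join(h),
        asite_span=(120, 123),
        isite_span=None,
        catalytic_positions=(40, 75, 120, 121, 122),
        dyad_positions=(40, 75),
        cog="COG3437",
    )
    return [ggdef, eal, hdgyp]


# ---------------------------------------------------------------------------
# reference proteins

@dataclass(frozen=True)
class PlantedDomain:
    """Where a domain copy sits inside a reference protein, with its
    functional residue positions mapped to protein coordinates."""

    kind: str
    span: tuple[int, int]
    asite_span: tuple[int, int]
    protected: tuple[int, ...]
    grade: str  # planted grade: intact | atypical | degenerate


@dataclass(frozen=True)
class ReferenceProtein:
    name: str
    sequence: str
    plasmid: bool
    tm_count: int
    expected_class: str
    domains: tuple[PlantedDomain, ...] = field(default=())


def _functional_positions(dom: ReferenceDomain) -> set[int]:
    pos = set(range(*dom.asite_span)) | set(dom.catalytic_positions)
    if dom.isite_span:
        pos |= set(range(*dom.isite_span))
    if dom.dyad_positions:
        pos |= set(dom.dyad_positions)
    if dom.key_glutamate is not None:
        pos.add(dom.key_glutamate)
    return pos


def _domain_copy(dom: ReferenceDomain, seed: int,
                 edits: dict[int, str] | None = None) -> tuple[str, set[int]]:
    protected = _functional_positions(dom)
    seq = list(
        mutate_to_identity(dom.sequence, DOMAIN_COPY_IDENTITY, 0.0, seed, protected)
    )
    for pos, res in (edits or {}).items():
        seq[pos] = res
    return "".join(seq), protected


# per-domain motif edits (domain coordinates) realising the planted grades
_EAL_ATYPICAL = {120: "A", 150: "G"}          # catalytic conservation 4/6
_EAL_DEGENERATE = {8: "Q", 10: "D", 70: "A",  # motif and key glutamate gone
                   95: "G", 120: "A", 150: "G"}
_GGDEF_ATYPICAL = {106: "Q"}                  # GGDEF -> GGDQF (one mismatch)
_HDGYP_DEGENERATE = {120: "A", 121: "S", 122: "R"}  # GYP lost

# layout grammar: ("sc", length) scaffold | ("tm", n_helices) |
#                 ("dom", kind, edits, planted_grade)
_PROTEIN_SPECS: dict[str, dict] = {
    # composite GGDEF+EAL, experimentally a DGC: EAL planted atypical
    "cdgA": dict(seed=201, plasmid=False, cls="DGC", layout=[
        ("sc", 200), ("dom", "GGDEF", {}, "intact"), ("sc", 12),
        ("dom", "EAL", _EAL_ATYPICAL, "atypical"), ("sc", 30)]),
    "cdgB": dict(seed=202, plasmid=False, cls="DGC", layout=[
        ("sc", 250), ("dom", "GGDEF", {}, "intact"), ("sc", 40)]),
    # membrane-bound composite with degenerate EAL
    "cdgC": dict(seed=203, plasmid=False, cls="DGC", layout=[
        ("tm", 10), ("sc", 120), ("dom", "GGDEF", {}, "intact"), ("sc", 10),
        ("dom", "EAL", _EAL_DEGENERATE, "degenerate"), ("sc", 20)]),
    "cdgD": dict(seed=204, plasmid=False, cls="DGC", layout=[
        ("sc", 60), ("dom", "GGDEF", {}, "intact"), ("sc", 60)]),
    "cdgE": dict(seed=205, plasmid=False, cls="DGC", layout=[
        ("sc", 150), ("dom", "GGDEF", {}, "intact"), ("sc", 40)]),
    # membrane-bound composite with both sites intact: bifunctional candidate
    "cdgF": dict(seed=206, plasmid=False, cls="bifunctional_candidate", layout=[
        ("tm", 10), ("sc", 120), ("dom", "GGDEF", {}, "intact"), ("sc", 10),
        ("dom", "EAL", {}, "intact"), ("sc", 20)]),
    # composite PDEs: EAL intact, GGDEF A-site atypical
    "rmdA": dict(seed=207, plasmid=False, cls="PDE", layout=[
        ("sc", 200), ("dom", "GGDEF", _GGDEF_ATYPICAL, "atypical"), ("sc", 12),
        ("dom", "EAL", {}, "intact"), ("sc", 30)]),
    "rmdB": dict(seed=208, plasmid=False, cls="PDE", layout=[
        ("tm", 6), ("sc", 60), ("dom", "GGDEF", _GGDEF_ATYPICAL, "atypical"),
        ("sc", 12), ("dom", "EAL", {}, "intact"), ("sc", 20)]),
    "hdgA": dict(seed=209, plasmid=False, cls="PDE", layout=[
        ("tm", 6), ("sc", 60), ("dom", "HD-GYP", {}, "intact"), ("sc", 30)]),
    "hdgB": dict(seed=210, plasmid=False, cls="degenerate", layout=[
        ("tm", 6), ("sc", 60), ("dom", "HD-GYP", _HDGYP_DEGENERATE, "degenerate"),
        ("sc", 30)]),
    # plasmid-encoded stand-alone GGDEF
    "pcdgG": dict(seed=211, plasmid=True, cls="DGC", layout=[
        ("sc", 60), ("dom", "GGDEF", {}, "intact"), ("sc", 40)]),
    # non-enzymatic c-di-GMP effector (DNA-binding regulator)
    "bldD": dict(seed=212, plasmid=False, cls="none", layout=[("sc", 167)]),
}


def build_reference_proteins() -> dict[str, ReferenceProtein]:
    """Construct the full synthetic reference protein set (deterministic)."""
    domains = {d.name: d for d in build_reference_domains()}
    out: dict[str, ReferenceProtein] = {}
    for name in TABLE_ORDER[:-1] + ("pcdgG", "bldD"):
        spec = _PROTEIN_SPECS[name]
        rng = np.random.default_rng(spec["seed"])
        parts: list[str] = []
        planted: list[PlantedDomain] = []
        tm_count = 0
        tm_spans: list[tuple[int, int]] = []
        offset = 0
        for i, piece in enumerate(spec["layout"]):
            if piece[0] == "sc":
                seg = rand_protein(piece[1], rng)
            elif piece[0] == "tm":
                seg = tm_block(piece[1], rng)
                tm_count = piece[1]
                tm_spans.append((offset, offset + len(seg)))
            else:
                _, kind, edits, grade = piece
                dom = domains[kind]
                seg, prot = _domain_copy(dom, spec["seed"] * 100 + i, edits)
                planted.append(
                    PlantedDomain(
                        kind=kind,
                        span=(offset, offset + len(seg)),
                        asite_span=(offset + dom.asite_span[0],
                                    offset + dom.asite_span[1]),
                        protected=tuple(sorted(offset + p for p in prot)),
                        grade=grade,
                    )
                )
            parts.append(seg)
            offset += len(seg)
        # keep the soluble regions soluble: no spurious hydrophobic windows
        # outside the planted TM blocks and functional residues
        keep = {p for d in planted for p in d.protected}
        for lo, hi in tm_spans:
            keep |= set(range(lo, hi))
        sequence = dehydrophobize("".join(parts), spec["seed"] * 7 + 1, keep)
        out[name] = ReferenceProtein(
            name=name,
            sequence=sequence,
            plasmid=spec["plasmid"],
            tm_count=tm_count,
            expected_class=spec["cls"],
            domains=tuple(planted),
        )
    return out


def reference_protein_set(include_plasmid: bool = False,
                          include_bldd: bool = True,
                          proteins: dict[str, ReferenceProtein] | None = None
                          ) -> dict[str, str]:
    """The name -> sequence map used as the ortholog reference anchor set
    (chromosomal entries; BldD included as the non-enzyme effector)."""
    proteins = proteins or load_reference_proteins()
    out = {}
    for name in CHROMOSOMAL_ORDER if include_bldd else CHROMOSOMAL_ORDER[:-1]:
        out[name] = proteins[name].sequence
    if include_plasmid:
        out["pcdgG"] = proteins["pcdgG"].sequence
    return out


# ---------------------------------------------------------------------------
# shipped fixture I/O

def _fasta(entries: dict[str, str]) -> str:
    lines = []
    for name, seq in entries.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    return "\n".join(lines) + "\n"


def dump_fixtures() -> dict[str, str]:
    """Render the shipped fixture files (FASTA + JSON sidecars) from the
    deterministic builders; used by the fixture-regeneration script and by
    the drift-guard test."""
    doms = build_reference_domains()
    prots = build_reference_proteins()
    dom_json = {
        "domains": [
            {
                "name": d.name,
                "source_protein": d.source_protein,
                "asite_span": list(d.asite_span),
                "isite_span": list(d.isite_span) if d.isite_span else None,
                "catalytic_positions": list(d.catalytic_positions),
                "dyad_positions": list(d.dyad_positions) if d.dyad_positions else None,
                "key_glutamate": d.key_glutamate,
                "cog": d.cog,
            }
            for d in doms
        ]
    }
    prot_json = {
        "proteins": [
            {
                "name": p.name,
                "plasmid": p.plasmid,
                "tm_count": p.tm_count,
                "expected_class": p.expected_class,
                "domains": [
                    {
                        "kind": d.kind,
                        "span": list(d.span),
                        "asite_span": list(d.asite_span),
                        "protected": list(d.protected),
                        "grade": d.grade,
                    }
                    for d in p.domains
                ],
            }
            for p in prots.values()
        ]
    }
    return {
        "reference_domains.synthetic.fasta": _fasta({d.name: d.sequence for d in doms}),
        "reference_domains.synthetic.json": json.dumps(dom_json, indent=1) + "\n",
        "reference_proteins.synthetic.fasta": _fasta(
            {p.name: p.sequence for p in prots.values()}
        ),
        "reference_proteins.synthetic.json": json.dumps(prot_json, indent=1) + "\n",
    }


def load_reference_proteins() -> dict[str, ReferenceProtein]:
    """Load the shipped reference proteins (FASTA + JSON sidecar)."""
    data = resources.files("panscan.data")
    meta = json.loads((data / "reference_proteins.synthetic.json").read_text())
    seqs: dict[str, str] = {}
    name = None
    for line in (data / "reference_proteins.synthetic.fasta").read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    out = {}
    for entry in meta["proteins"]:
        out[entry["name"]] = ReferenceProtein(
            name=entry["name"],
            sequence=seqs[entry["name"]],
            plasmid=entry["plasmid"],
            tm_count=entry["tm_count"],
            expected_class=entry["expected_class"],
            domains=tuple(
                PlantedDomain(
                    kind=d["kind"],
                    span=tuple(d["span"]),
                    asite_span=tuple(d["asite_span"]),
                    protected=tuple(d["protected"]),
                    grade=d["grade"],
                )
                for d in entry["domains"]
            ),
        )
    return out
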