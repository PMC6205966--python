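"""Reading and writing annotated genomes and proteomes.

Genomes are handled as ordered lists of protein-coding genes per replicon.
Coordinates are converted to 0-based half-open at parse time (the single
conversion point from GenBank's 1-based inclusive convention) and genes are
ranked by start coordinate within their replicon; all neighborhood logic
downstream works on those ranks, never on nucleotide distances.

Replicons are classified as ``plasmid`` when the GenBank record carries a
``/plasmid`` source qualifier or the word "plasmid" in its DEFINITION line,
as ``chromosome`` on "chromosome"/"complete genome", else ``unknown``.
Only explicit plasmids are dropped by ``exclude_plasmids``; ``unknown``
replicons are kept, mirroring record-level plasmid removal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .align import VALID_RESIDUES

logger = logging.getLogger(__name__)

REPLICON_KINDS = ("chromosome", "plasmid", "unknown")


@dataclass
class GeneRecord:
    """One protein-coding gene: position, strand and translated product."""

    locus_tag: str
    product: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: int  # +1 / -1
    replicon_id: str
    replicon_kind: str
    order_index: int
    protein: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.locus_tag}: bad coordinates {self.start}..{self.end}")
        if self.strand not in (+1, -1):
            raise ValueError(f"{self.locus_tag}: strand must be +1/-1")
        if not self.protein:
            raise ValueError(f"{self.locus_tag}: empty protein")


@dataclass
class Replicon:
    replicon_id: str
    kind: str
    genes: list[GeneRecord] = field(default_factory=list)


@dataclass
class Genome:
    """All replicons of one species, genes ordered by start within each."""

    species_id: str
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        tags = [g.locus_tag for r in self.replicons for g in r.genes]
        if len(tags) != len(set(tags)):
            raise ValueError(f"{self.species_id}: duplicate locus_tags")

    def genes(self):
        for rep in self.replicons:
            yield from rep.genes

    def find(self, locus_tag: str) -> tuple[Replicon, GeneRecord]:
        for rep in self.replicons:
            for g in rep.genes:
                if g.locus_tag == locus_tag:
                    return rep, g
        raise KeyError(f"locus_tag {locus_tag!r} not in genome {self.species_id}")

    def proteome(self) -> "Proteome":
        return Proteome(
            species_id=self.species_id,
            entries={g.locus_tag: g.protein for g in self.genes()},
        )


@dataclass
class Proteome:
    species_id: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        for tag, seq in self.entries.items():
            if not seq:
                raise ValueError(f"{tag}: empty sequence")
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise ValueError(f"{tag}: invalid residues {sorted(bad)!r}")


def _replicon_kind(record: SeqRecord) -> str:
    for feat in record.features:
        if feat.type == "source" and "plasmid" in feat.qualifiers:
            return "plasmid"
    definition = (record.description or "").lower()
    if "plasmid" in definition:
        return "plasmid"
    if "chromosome" in definition or "complete genome" in definition:
        return "chromosome"
    return "unknown"


def read_genbank(path: str | Path, exclude_plasmids: bool = True,
                 species_id: str | None = None) -> Genome:
    """Parse a (multi-record) GenBank flat file into a :class:`Genome`.

    One replicon per record.  CDS features lacking both a ``/translation``
    qualifier and an extractable nucleotide sequence are skipped with a
    logged warning.  With ``exclude_plasmids`` (the default) replicons
    classified as plasmids are dropped.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records in {path}")

    replicons: list[Replicon] = []
    for record in records:
        kind = _replicon_kind(record)
        if exclude_plasmids and kind == "plasmid":
            logger.info("dropping plasmid record %s", record.id)
            continue
        genes: list[GeneRecord] = []
        for feat in record.features:
            if feat.type != "CDS":
                continue
            tag = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("protein_id", [None])[0]
                or f"{record.id}_CDS{len(genes)}"
            )
            protein = feat.qualifiers.get("translation", [None])[0]
            if protein is None:
                try:
                    protein = str(
                        feat.extract(record.seq).translate(table=11, cds=False)
                    ).rstrip("*")
                except Exception:
                    protein = None
            if not protein:
                logger.warning(
                    "%s: CDS %s lacks translation and sequence; skipped",
                    record.id, tag,
                )
                continue
            loc = feat.location
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    product=feat.qualifiers.get("product", [""])[0],
                    start=int(loc.start),  # Biopython is already 0-based half-open
                    end=int(loc.end),
                    strand=int(loc.strand or 1),
                    replicon_id=record.id,
                    replicon_kind=kind,
                    order_index=0,
                    protein=protein.upper().rstrip("*"),
                )
            )
        genes.sort(key=lambda g: (g.start, g.end, g.locus_tag))
        for i, g in enumerate(genes):
            g.order_index = i
        replicons.append(Replicon(replicon_id=record.id, kind=kind, genes=genes))

    return Genome(species_id=species_id or path.stem, replicons=replicons)


def read_fasta_proteome(path: str | Path, species_id: str) -> Proteome:
    """Read a protein FASTA; the header token before the first whitespace is
    the locus_tag, terminal '*' stops are stripped."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tag = rec.id
        if tag in entries:
            raise ValueError(f"duplicate FASTA header: {tag}")
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence for {tag}")
        entries[tag] = seq
    return Proteome(species_id=species_id, entries=entries)


def write_fasta_proteome(proteome: Proteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag, seq in proteome.entries.items():
            fh.write(f">{tag}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def neighborhood(genome: Genome, locus_tag: str, k: int):
    """The 2k+1 gene-rank window centered on ``locus_tag``.

    Returns a list of ``(offset, GeneRecord | None)`` for offsets -k..+k;
    ``None`` flags positions beyond the replicon bounds.  Neighbors are
    taken strictly by order_index on the anchor's replicon, strand-agnostic.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rep, anchor = genome.find(locus_tag)
    out = []
    for off in range(-k, k + 1):
        idx = anchor.order_index + off
        out.append((off, rep.genes[idx] if 0 <= idx < len(rep.genes) else None))
    return out


# ---------------------------------------------------------------------------
# internal JSON dump (documented schema, round-trip safe)

def genome_to_json(genome: Genome) -> str:
    """Serialize to the internal JSON schema::

        {"species_id": ..., "replicons": [
            {"replicon_id": ..., "kind": ..., "genes": [
                {"locus_tag", "product", "start", "end", "strand", "protein"},
            ...]}]}

    order_index is implicit in gene order.
    """
    doc = {
        "species_id": genome.species_id,
        "replicons": [
            {
                "replicon_id": rep.replicon_id,
                "kind": rep.kind,
                "genes": [
                    {
                        "locus_tag": g.locus_tag,
                        "product": g.product,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "protein": g.protein,
                    }
                    for g in rep.genes
                ],
            }
            for rep in genome.replicons
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def genome_from_json(text: str) -> Genome:
    doc = json.loads(text)
    replicons = []
    for rdoc in doc["replicons"]:
        genes = [
            GeneRecord(
                locus_tag=g["locus_tag"],
                product=g["product"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                replicon_id=rdoc["replicon_id"],
                replicon_kind=rdoc["kind"],
                order_index=i,
                protein=g["protein"],
            )
            for i, g in enumerate(rdoc["genes"])
        ]
        replicons.append(
            Replicon(replicon_id=rdoc["replicon_id"], kind=rdoc["kind"], genes=genes)
        )
    return Genome(species_id=doc["species_id"], replicons=replicons)


# ---------------------------------------------------------------------------
# GenBank writer (used by the simulator; deterministic output)

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN",
}


def write_genbank(genome: Genome, path: str | Path) -> None:
    """Write a Genome as a multi-record GenBank flat file.

    Nucleotide sequence is a deterministic back-translation (one fixed codon
    per residue) padded with 'A'; CDS features carry /translation qualifiers
    so parsing never depends on the nucleotide sequence.  The LOCUS date is
    fixed so that equal genomes yield byte-identical files.
    """
    records = []
    for rep in genome.replicons:
        length = max((g.end for g in rep.genes), default=60) + 60
        seq_chars = ["A"] * length
        for g in rep.genes:
            nt = "".join(_CODON[a] for a in g.protein) + "TAA"
            nt = nt[: g.end - g.start].ljust(g.end - g.start, "A")
            if g.strand == -1:
                nt = str(Seq(nt).reverse_complement())
            seq_chars[g.start : g.end] = list(nt)
        record = SeqRecord(
            Seq("".join(seq_chars)),
            id=rep.replicon_id,
            name=rep.replicon_id[:16],
            description=(
                f"{genome.species_id} {rep.replicon_id}"
                + (" plasmid" if rep.kind == "plasmid" else ", complete genome")
            ),
            annotations={
                "molecule_type": "DNA",
                "topology": "linear",
                "data_file_division": "BCT",
                "date": "23-OCT-2018",
            },
        )
        src = SeqFeature(FeatureLocation(0, length, strand=1), type="source")
        if rep.kind == "plasmid":
            src.qualifiers["plasmid"] = [rep.replicon_id]
        record.features.append(src)
        for g in rep.genes:
            feat = SeqFeature(
                FeatureLocation(g.start, g.end, strand=g.strand), type="CDS"
            )
            feat.qualifiers["locus_tag"] = [g.locus_tag]
            if g.product:
                feat.qualifiers["product"] = [g.product]
            feat.qualifiers["translation"] = [g.protein]
            record.features.append(feat)
        records.append(record)
    SeqIO.write(records, str(path), "genbank")
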