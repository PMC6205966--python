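import pytest

from panscan.genome_io import GeneRecord, Genome, Replicon
from panscan.references import build_reference_domains, load_reference_proteins


@pytest.fixture(scope="session")
def domains():
    return build_reference_domains()


@pytest.fixture(scope="session")
def domain_by_name(domains):
    return {d.name: d for d in domains}


@pytest.fixture(scope="session")
def ref_proteins():
    return load_reference_proteins()


def make_genome(species_id="toy", replicon_specs=None):
    """Build a Genome from [(replicon_id, kind, [(tag, protein), ...]), ...];
    genes are laid out head-to-tail on the + strand."""
    replicon_specs = replicon_specs or []
    replicons = []
    for rid, kind, genes in replicon_specs:
        records = []
        pos = 100
        for i, (tag, protein) in enumerate(genes):
            end = pos + 3 * len(protein) + 3
            records.append(
                GeneRecord(
                    locus_tag=tag, product="", start=pos, end=end, strand=1,
                    replicon_id=rid, replicon_kind=kind, order_index=i,
                    protein=protein,
                )
            )
            pos = end + 50
        replicons.append(Replicon(replicon_id=rid, kind=kind, genes=records))
    return Genome(species_id=species_id, replicons=replicons)


@pytest.fixture
def toy_genome():
    return make_genome(
        "toy",
        [
            ("chr1", "chromosome",
             [("g1", "MKTAYIAKQR"), ("g2", "MEEPQSDPSV"), ("g3", "MGDVEKGKKI")]),
            ("plas1", "plasmid", [("p1", "MSKGEELFTG")]),
        ],
    )
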