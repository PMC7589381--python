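import numpy as np
import pytest

from polyko._seq import random_dna
from polyko.guides import design_guides
from polyko.paralogs import ParalogRecord
from polyko.synthetic import FamilySpec, PlantedSite, simulate_gene_family

PROTO = "GTCGACTGGACATCAGCTTG"  # GC 55%


@pytest.fixture(scope="session")
def snp_family():
    """Four-copy family with a planted guide site; copy 1 carries the
    diagnostic SNP at protospacer position 10 from the PAM."""
    site = PlantedSite(PROTO, "TGG", snp_paralog_index=1, snp_position_from_pam=10)
    return simulate_gene_family(
        FamilySpec(ancestral_length=600, n_copies=4,
                   target_identity_range=(0.92, 0.99), site_spec=site,
                   seed=7, name="fam")
    )


@pytest.fixture(scope="session")
def planted_genome(snp_family):
    """Each family member embedded in a contig with random flanks, plus a
    decoy contig; member coordinates updated to the planted locations."""
    rng = np.random.default_rng(99)
    genome = {}
    members = []
    for m in snp_family.members:
        genome[m.contig] = random_dna(300, rng) + m.cds_sequence + random_dna(300, rng)
        members.append(ParalogRecord(
            id=m.id, contig=m.contig, start=300, end=300 + len(m.cds_sequence),
            strand="+", cds_sequence=m.cds_sequence,
        ))
    genome["decoy1"] = random_dna(3000, rng)
    snp_family.members = members
    return genome


@pytest.fixture(scope="session")
def designed_guide(snp_family, planted_genome):
    accepted = design_guides(snp_family, planted_genome)
    assert accepted, "fixture family must yield at least one guide"
    return accepted[0]
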