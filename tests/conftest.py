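import pytest

from subrvis.regions import DomainAlignment, GeneModel
from subrvis.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted intolerance, shared across tests."""
    return simulate_cohort(SimConfig(n_genes=60), seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal: suppression and enrichment both 1."""
    return simulate_cohort(
        SimConfig(n_genes=60, suppression=1.0, pathogenic_enrichment=1.0), seed=13
    )


@pytest.fixture
def gene_900():
    """Single-exon plus-strand gene with a 900 nt CDS."""
    return GeneModel("G1", "chr1", "+", ((1000, 1900),))


@pytest.fixture
def three_exon_gene():
    """Plus-strand gene with coding exons of lengths 100, 200, 50."""
    return GeneModel("G3", "chr2", "+", ((0, 100), (300, 500), (700, 750)))


@pytest.fixture
def minus_gene():
    """Minus-strand gene: transcription order is 3'-most genomic first."""
    return GeneModel("GM", "chr3", "-", ((700, 750), (300, 500), (0, 100)))


def make_alignment(gene_id="G1", domain_id="d1", aa_start=10, aa_end=50,
                   evalue=1e-6, score=100.0):
    return DomainAlignment(gene_id, domain_id, aa_start, aa_end, evalue, score)
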