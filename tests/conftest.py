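import pytest

from splicescape.genome_model import GeneModel
from splicescape.junction_io import JunctionEvidence
from splicescape.synthetic_data import SimulationConfig, simulate_bundle


def make_junction(
    chrom="Chr01",
    strand="+",
    start=100,
    end=200,
    reads=10,
    distinct=None,
    overhang=20,
    individual="PT01",
):
    return JunctionEvidence(
        chrom=chrom,
        strand=strand,
        intron_start=start,
        intron_end=end,
        read_count=reads,
        distinct_positions=reads if distinct is None else distinct,
        min_overhang=overhang,
        individual_id=individual,
    )


@pytest.fixture
def three_exon_gene():
    """'+'-strand gene with exons 0-100, 200-300, 400-500 (introns 100-200, 300-400)."""
    return GeneModel("G1", "Chr01", "+", {"G1.1": [(0, 100), (200, 300), (400, 500)]})


@pytest.fixture
def toy_genes(three_exon_gene):
    """Two genes on opposite strands, the second with four exons."""
    g2 = GeneModel(
        "G2",
        "Chr01",
        "-",
        {"G2.1": [(1000, 1100), (1200, 1300), (1400, 1500), (1600, 1700)]},
    )
    return {"G1": three_exon_gene, "G2": g2}


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete 20-individual synthetic bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=7, n_genes=40)
    paths = simulate_bundle(cfg, out)
    paths["cfg"] = cfg
    return paths
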