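import pytest

from hotspotscan import SimConfig, Thresholds, load_specimen_fixture, simulate_dataset
from hotspotscan.core_io import PhasedGeneAlignment


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def fixture_records():
    return load_specimen_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded two-species dataset with ground truth."""
    return simulate_dataset(SimConfig(n_genes=30, seed=11))


def make_alignment(seqs_by_specimen, gene_id="g1", exons=None, is_mito=False):
    """Build a PhasedGeneAlignment from {specimen: (h1_seq, h2_seq)}."""
    sequences = {}
    for sid, (h1, h2) in seqs_by_specimen.items():
        sequences[(sid, 1)] = h1
        sequences[(sid, 2)] = h2
    return PhasedGeneAlignment(gene_id, sequences, exons or [], is_mito=is_mito)


@pytest.fixture
def two_by_two():
    """Hand-built 2+2-specimen alignment (100 columns, all comparable) with
    known pairwise difference counts:

    intra A: a1.h1 vs a1.h2 -> 1;  intra B: b1.h1 vs b1.h2 -> 2
    inter:   {a1.h1-b1.h1: 3, a1.h1-b1.h2: 5, a1.h2-b1.h1: 4, a1.h2-b1.h2: 6}
    """
    base = list("ACGT" * 25)

    def variant(positions):
        s = list(base)
        for p in positions:
            s[p] = "T" if s[p] != "T" else "A"
        return "".join(s)

    aln = make_alignment({
        "a1": (variant([]), variant([0])),
        "b1": (variant([10, 11, 12]), variant([10, 11, 12, 13, 14])),
    })
    species = {"a1": "A", "b1": "B"}
    return aln, species
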