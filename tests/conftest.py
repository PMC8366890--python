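import numpy as np
import pytest

from hapassort.distances import DistanceMatrix
from hapassort.seqio import Alignment, MetadataTable, make_dataset
from hapassort.simulate import SimConfig, SiteSpec, simulate_dataset


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences(
        ("s1", "s2", "s3", "s4"),
        (
            "ACGTACGTACGGTACCTTAGACGTTAGC",
            "ACGTACGTACAGTACCTTAGACGCTAGC",
            "ATGTACGAACGGTTCCTTAGACGTTAAC",
            "ACGAACGTACGGTACCTCAGACTTTAGC",
        ),
    )


@pytest.fixture
def three_taxon_dm():
    vals = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
    return DistanceMatrix(("A", "B", "C"), vals, "p")


@pytest.fixture
def small_sim():
    """A compact simulated dataset: 2 sites per habitat class, n=24."""
    sites = (
        SiteSpec("off1", "offshore_reef", 6),
        SiteSpec("off2", "offshore_reef", 6),
        SiteSpec("in1", "inshore_reef", 5),
        SiteSpec("gb1", "grass_bed", 7),
    )
    return simulate_dataset(SimConfig(sites=sites, seed=11))


@pytest.fixture
def two_sample_dataset():
    aln = Alignment.from_sequences(("a1", "a2"), ("ACGT", "ACGA"))
    meta = MetadataTable.from_records(
        [
            {"sample_id": "a1", "site": "x", "habitat": "offshore reef", "region": "keys"},
            {"sample_id": "a2", "site": "x", "habitat": "offshore reef", "region": "keys"},
        ]
    )
    return make_dataset(aln, meta)
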