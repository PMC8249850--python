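import pytest

from ampliclass.refdb_io import Lineage, ReferenceDB, RefRecord
from ampliclass.class_weights import ClassWeights, uniform_weights
from ampliclass.simulate import SynthConfig, simulate_all, simulate_reference


def lin(*labels: str) -> Lineage:
    return Lineage(tuple(labels))


def full_lineage(genus: str, species: str) -> Lineage:
    """A complete 7-rank lineage sharing everything above genus."""
    return lin("Bacteria", "P1", "C1", "O1", "F1", genus, species)


@pytest.fixture
def toy_refdb() -> ReferenceDB:
    """Four species in two genera with distinct, hand-written sequences."""
    return ReferenceDB(
        {
            "r1": RefRecord("ACGTACGTACGTACGT", full_lineage("G1", "s1")),
            "r2": RefRecord("TTTTCCCCGGGGAAAA", full_lineage("G1", "s2")),
            "r3": RefRecord("GGGGGGGGTTTTTTTT", full_lineage("G2", "s3")),
            "r4": RefRecord("CCCCAAAATTTTGGGG", full_lineage("G2", "s4")),
        }
    )


@pytest.fixture(scope="session")
def small_synth():
    """The clean study conditions: ~50 species, no shared sequences, no read errors."""
    cfg = SynthConfig(p_share=0.0, error_rate=0.0, n_samples=10,
                      reads_per_sample=100, seed=11)
    return (cfg, *simulate_all(cfg))


@pytest.fixture(scope="session")
def tiny_synth_refdb():
    cfg = SynthConfig(branching=(1, 2, 1, 1, 1, 2, 3), seed=5)
    return simulate_reference(cfg)
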