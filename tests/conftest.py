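import numpy as np
import pytest

from comutsig.cohort_io import MutationRecord, MutationTable
from comutsig.simulate import SimConfig, simulate_cohort


@pytest.fixture
def toy_mutations() -> MutationTable:
    """Three samples, three genes, mixed variant classes."""
    return MutationTable(
        [
            MutationRecord("s1", "TP53", "chr17", 100, "C", "T", "SNV",
                           context="ACA"),
            MutationRecord("s1", "TP53", "chr17", 150, "G", "A", "SNV",
                           context="TGT"),
            MutationRecord("s1", "APC", "chr5", 200, "A", "-", "DEL"),
            MutationRecord("s2", "APC", "chr5", 300, "T", "G", "SNV",
                           context="ATG"),
            MutationRecord("s2", "KRAS", "chr12", 400, "G", "T", "CNV"),
            MutationRecord("s3", "KRAS", "chr12", 500, "C", "G", "SNV",
                           context="GCC"),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-cluster cohort small enough for per-test reuse."""
    clusters = SimConfig().clusters
    genes = tuple(g for c in clusters for g in c.genes) + ("TP53", "APC",
                                                           "KRAS", "SMAD4")
    cfg = SimConfig(n_samples=80, genes=genes, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
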