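import numpy as np
import pandas as pd
import pytest

from mirror21.diffexpr import CountMatrix
from mirror21.regions import GeneRecord, GenomicInterval
from mirror21.simulate import SimConfig, simulate_experiment

#: the two ring-chromosome deletion intervals (1-based closed, hg38)
DELETIONS = (
    GenomicInterval("21", 41_994_799, 43_447_106, "deletion_1"),
    GenomicInterval("21", 44_361_567, 46_944_323, "deletion_2"),
)


@pytest.fixture(scope="session")
def deletions():
    return list(DELETIONS)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment in the study layout (shared across tests)."""
    config = SimConfig(seed=42, n_genes=400, n_deleted_genes=20)
    return simulate_experiment(config)


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix: 5 genes x 3 samples, all positive."""
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 30, 40, 50],
            "s2": [12, 18, 33, 37, 55],
            "s3": [ 8, 25, 27, 45, 60],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "line": ["L1", "L2", "L3"],
            "genotype": ["control", "control", "control"],
            "replicate": [1, 1, 1],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return CountMatrix(counts, samples)


def random_gene_records(rng: np.random.Generator, n: int) -> list[GeneRecord]:
    """Toy genes scattered on chr20/21/22 around the deletion neighbourhood."""
    records = []
    for i in range(n):
        chrom = rng.choice(["20", "21", "chr21", "22"])
        start = int(rng.integers(1, 50_000_000))
        records.append(
            GeneRecord(
                gene_id=f"toy{i}",
                gene_name=f"toy{i}",
                chromosome=str(chrom),
                start=start,
                end=start + int(rng.integers(1, 500_000)),
            )
        )
    return records
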