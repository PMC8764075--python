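"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    from hicdyn import simulate_genome

    return simulate_genome(n_chroms=1, chrom_length_bp=20_000_000,
                           bin_size_bp=40_000, n_genes=200, seed=0)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    from hicdyn import simulate_architecture

    return simulate_architecture(small_genome, flip_fraction=0.10, seed=1)


@pytest.fixture(scope="session")
def small_omics(small_genome, small_truth):
    from hicdyn import simulate_chip_and_expression

    return simulate_chip_and_expression(small_genome, small_truth, seed=2)


def toy_matrix(counts, chrom="chr1", bin_size=10_000):
    from hicdyn import ContactMatrix

    return ContactMatrix(chrom=chrom, bin_size=bin_size,
                         counts=np.asarray(counts, dtype=float))


@pytest.fixture
def genes_frame():
    return pd.DataFrame({
        "gene": ["g1", "g2"],
        "chrom": ["chr1", "chr1"],
        "tss": [100_000, 400_000],
        "strand": ["+", "-"],
    })
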