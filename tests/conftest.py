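import numpy as np
import pytest

from regburden.mutability import BASES, MutabilityTable
from regburden.synthetic_data import SyntheticConfig, simulate_study


def make_uniform_table(rate: float = 1e-8) -> MutabilityTable:
    """Every (context, alt) entry shares one rate: site totals are 3*rate."""
    entries = {
        (a + m + b, alt): rate
        for m in "CT"
        for a in BASES
        for b in BASES
        for alt in BASES
        if alt != m
    }
    return MutabilityTable(entries, provenance="uniform test table")


@pytest.fixture(scope="session")
def uniform_table() -> MutabilityTable:
    return make_uniform_table()


@pytest.fixture(scope="session")
def default_table() -> MutabilityTable:
    return MutabilityTable.default()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7,
        chrom_lengths={"chr1": 600_000, "chr2": 600_000},
        genes_per_chrom=6,
        n_planted_specific=8,
        n_planted_shared=12,
        n_noise_enhancers=15,
        n_probands_case=10,
        n_probands_control=10,
        mean_dnms_per_proband=30,
        mean_dnms_control=30,
        burden_multiplier=3.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
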