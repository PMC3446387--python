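import numpy as np
import pytest

from ampliconscan import CbsParams, SimConfig, simulate_cohort

AMPLICON_LOCUS = ("chr19", 27_800_000, 32_900_000)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort for fast pipeline-level tests."""
    return SimConfig(
        n_samples=40,
        n_clones=400,
        chrom_sizes={"chr19": 59_130_000, "chr2": 35_000_000},
        amplicon_prevalence=0.15,
        n_genes=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def fast_cbs() -> CbsParams:
    return CbsParams(alpha=0.01, n_perm=500, min_width=2, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
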