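import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracle helpers

from enhancerenrich.simulate import EnhancerSetSpec, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 4 x 200 kb chromosomes, 8,000 SNPs, one 3-fold
    enriched set and one decoy, tuned like the reference scenario."""
    return SimulationConfig(
        n_chrom=4,
        chrom_length=200_000,
        n_snps=8_000,
        sets=(
            EnhancerSetSpec("enriched", genome_fraction=0.05, enrichment_fold=3.0, mean_length=500),
            EnhancerSetSpec("decoy", genome_fraction=0.05, enrichment_fold=1.0, mean_length=500),
        ),
        causal_fraction=0.02,
        effect_scale=1.4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
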