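import logging

import numpy as np
import pytest

from lymphmap.sim import SimConfig, simulate_cohort

logging.getLogger("lymphmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but structurally complete cohort: 4 chromosomes, LD blocks,
    planted recessive haplotype, multi-generation pedigree."""
    return SimConfig(
        seed=11,
        n_chromosomes=4,
        snps_per_chromosome=80,
        risk_chromosome=2,
        risk_haplotype_span=(40, 49),
        n_founders=16,
        n_generations=3,
        n_offspring_per_generation=40,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-size cohort (330 dogs, 38 chromosomes) shared by tests
    that need the full study conditions."""
    return simulate_cohort(SimConfig(seed=7))
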