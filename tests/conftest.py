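import numpy as np
import pandas as pd
import pytest

from thymoatlas.synthetic_data import (
    CohortConfig,
    GenomeConfig,
    StageProfileConfig,
    default_cohort_config,
    generate_genome_model,
    generate_stage_profiles,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """One default simulated cohort shared across the suite (seed 1)."""
    return simulate_cohort(default_cohort_config(), seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome_model(
        GenomeConfig(chromosomes=(("chr1", 2_000_000),), genes_per_chromosome=50, seed=0)
    )


@pytest.fixture(scope="session")
def small_stage_data(small_genome):
    cfg = StageProfileConfig(n_peaks=800, donors_per_stage=3)
    return generate_stage_profiles(small_genome, cfg, seed=11)
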