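import numpy as np
import pytest

from pleiomap.synthetic import (
    SimulationConfig,
    default_config,
    simulate_cohort,
    simulate_ld_genome,
)


@pytest.fixture(scope="session")
def small_config():
    cfg = SimulationConfig(
        seed=11, n_ld_blocks=4, variants_per_block=40, genes_per_block=2,
        n_disease_studies=12, n_measurement_studies=2, n_molqtl_studies=8,
    )
    from pleiomap._utils import named_rng
    from pleiomap.synthetic import default_pleiotropy_plan

    cfg.pleiotropy_plan = default_pleiotropy_plan(8, named_rng(11, "pleiotropy_plan"))
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_ld_genome(small_config)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(default_config(5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
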