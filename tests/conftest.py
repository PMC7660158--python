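import numpy as np
import pytest

from proxymr import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort under default (active-effect) conditions."""
    return generate_cohort(SimulationConfig(n_families=20_000, seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every maternal effect switched off."""
    config = SimulationConfig(
        n_families=20_000,
        beta_cigs_bw_g1=0.0,
        beta_cigs_bw_g2=0.0,
        adult_outcome_specs=(),
        seed=202,
    )
    return generate_cohort(config)
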