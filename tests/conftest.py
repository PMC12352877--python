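import numpy as np
import pytest

from epixpress.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two patients × 1,200 genes — enough structure for model behaviour
    tests while staying fast."""
    return generate_cohort(SyntheticConfig(n_genes=1200, n_patients=2, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions: 2 patients × 5,000 genes."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
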