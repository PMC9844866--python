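import numpy as np
import pytest

from writersig.datasets import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """The standard planted-structure study cohort: 500 genes, 20
    informative at 2 sd, survival driven by the signature (log-HR 1)."""
    return generate_cohort(CohortConfig(
        n_samples=120, n_genes=500, n_informative=20,
        effect_size=2.0, log_hazard_ratio=1.0, seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """No expression signal, no survival signal."""
    return generate_cohort(CohortConfig(
        n_samples=120, n_genes=500, n_informative=20,
        effect_size=0.0, log_hazard_ratio=0.0, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
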