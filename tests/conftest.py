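import numpy as np
import pytest

from ectomark.synthetic_data import SimConfig, simulate_tumor_cohort


@pytest.fixture(scope="session")
def small_config():
    """Small study: 20 candidates among 60 genes, 3 prognostic, 200 patients."""
    return SimConfig(
        n_genes=60,
        n_tissue_specific=15,
        n_ectopic_candidates=20,
        n_true_prognostic=3,
        n_patients=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_tumor_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
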