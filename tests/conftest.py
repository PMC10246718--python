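import numpy as np
import pytest

from tepdx.simulate import CohortSpec, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Two-cohort study small enough for fast end-to-end exercises."""
    return SimConfig(
        n_genes=400,
        cohorts=(CohortSpec("tr", 60, 40, 20), CohortSpec("va", 30, 20, 10)),
        n_signal_genes=25,
        n_age_genes=15,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
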