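import numpy as np
import pytest

from mmsurv.simulate import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Desk-scale cohort configuration shared across tests."""
    return CohortSimConfig(
        n_patients=60,
        n_wsi_patches=4,
        n_us_tokens=3,
        stream_dims={
            "wsi_deep": 8,
            "wsi_morph": 5,
            "wsi_top": 6,
            "us_deep": 8,
            "us_omic": 5,
            "us_text": 7,
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim_config):
    cohort, truth = simulate_cohort(tiny_sim_config)
    return cohort, truth, tiny_sim_config.clinical_schema


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
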