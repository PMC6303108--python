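import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully coupled cohort shared by pipeline-level tests."""
    from replayplan.neurogen import generate_cohort

    return generate_cohort(n_participants=8, seed=42)


@pytest.fixture(scope="session")
def default_localizer():
    """One localizer at default SNR with its generator parameters."""
    from replayplan.neurogen import NeuroGenParams, generate_localizer

    params = NeuroGenParams(selectivity_amplitude=2.0, noise_sd=1.0)
    return params, generate_localizer(params, np.random.default_rng(7))
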