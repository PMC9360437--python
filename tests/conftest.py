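import numpy as np
import pytest

from cachemet import synthetic as syn


@pytest.fixture(scope="session")
def noise_free_config():
    """Noise-free generator settings with a flat RER (fed == fasted) so
    exact round-trip identities can be asserted."""
    return syn.SimConfig(noise_sd=0.0, rer_fed=0.72, rer_fasted=0.72,
                         weight_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_trace(noise_free_config):
    trace, truth = syn.simulate_cage_trace(noise_free_config, seed=7)
    return trace, truth


@pytest.fixture(scope="session")
def noisy_trace():
    cfg = syn.SimConfig(noise_sd=0.05)
    return syn.simulate_cage_trace(cfg, seed=42)


@pytest.fixture(scope="session")
def cohort_noise_free():
    cfg = syn.SimConfig(n_animals=40, weight_noise_sd=0.0, seed=5)
    return syn.simulate_weight_trajectories(cfg)
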