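import pytest
from hypothesis import settings

from poolmaf import PoolSimConfig, simulate_experiment

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_experiment():
    """A small but non-trivial simulated experiment shared across tests."""
    config = PoolSimConfig(L=400, N=10, theta=0.01, mean_depth=15.0, seed=42,
                           chrom="mini")
    truth, reads = simulate_experiment(config)
    return config, truth, reads
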