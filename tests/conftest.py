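import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirarmkit import synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimConfig:
    """A fast configuration for module-level tests."""
    return synthetic.SimConfig(seed=11, n_patients=30, n_arm_pairs=60, n_genes=400,
                               n_enriched=40, n_reads=1500)


@pytest.fixture(scope="session")
def references(small_config):
    """Mature miRNAs, precursors and transcripts with planted sites."""
    return synthetic.gen_references(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
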