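import numpy as np
import pytest

from alphagate.synthetic import SimulationConfig, _rng_for, simulate_subject_epochs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture(scope="session")
def small_config():
    """A fast study configuration: full montage, few epochs."""
    return SimulationConfig(
        n_per_group=5, n_epochs_per_session=8, artifact_rate=0.0, seed=42
    )


@pytest.fixture(scope="session")
def small_epochs(small_config):
    """One simulated subject-session reused across read-only tests."""
    return simulate_subject_epochs(
        small_config, 0.0, "pre", _rng_for(small_config, 1, 0, 0)
    )
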