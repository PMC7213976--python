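import numpy as np
import pytest

from chunktrack import stimuli
from chunktrack.synth import SensorLayout, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vocabulary():
    return stimuli.build_vocabulary(0)


@pytest.fixture(scope="session")
def small_layout():
    return SensorLayout(n_positions=4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small high-SNR rule-based dataset reused across tests."""
    config = SyntheticConfig(
        n_participants=4,
        trials_per_cell=6,
        n_positions=4,
        source_model="rule_based_chunking",
        snr_db=15.0,
        seed=7,
    )
    return generate_dataset(config)
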