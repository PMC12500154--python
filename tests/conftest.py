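import numpy as np
import pytest

from saccatt.synthgen import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def tiny_experiment():
    """3 participants × 60 trials/task with planted ground truth."""
    cfg = SimConfig(n_participants=3, trials_per_task=60, seed=7)
    datasets, truth = generate_experiment(cfg)
    return cfg, datasets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
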