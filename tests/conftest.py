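import numpy as np
import pytest

from ecgbeats.synthetic import NoiseSpec, SyntheticConfig, synth_record


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free 300-beat record with ground-truth annotations."""
    cfg = SyntheticConfig(n_beats=300, noise=NoiseSpec.none(), seed=42)
    return cfg, synth_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """A 200-beat record with the default noise mix."""
    cfg = SyntheticConfig(n_beats=200, seed=7)
    return cfg, synth_record(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
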