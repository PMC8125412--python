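import numpy as np
import pytest

from glimpse import GazeDataset, Scenario


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_obs=None, n_frames=None, missing=0.2) -> GazeDataset:
    """Small random normalized dataset with missing samples."""
    n = n_obs or int(rng.integers(1, 6))
    t = n_frames or int(rng.integers(1, 21))
    pos = rng.random((n, t, 2))
    pos[rng.random((n, t)) < missing] = np.nan
    return GazeDataset(pos, width=1.0, height=1.0, normalized=True)


@pytest.fixture
def autocorrelated_scenario():
    """Fixed mid-size scenario with persistent attending states."""
    return Scenario(n_observers=12, n_frames=120, alpha=0.6, switch_prob=0.05, seed=11)
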