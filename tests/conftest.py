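import numpy as np
import pytest

from soundbrain.synthetic import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four 20-TR runs, 4 targets, moderate noise: the workhorse fixture."""
    spec = SyntheticSpec(n_subjects=1, seasons=1, episodes_per_season=2,
                         n_tr=20, n_targets=4, kernel_size=2,
                         noise_sigma=0.5, plant_rank=16, seed=5)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_noiseless():
    """Same shape as tiny_dataset but sigma = 0 (exact planted signal)."""
    spec = SyntheticSpec(n_subjects=1, seasons=1, episodes_per_season=2,
                         n_tr=20, n_targets=4, kernel_size=2,
                         noise_sigma=0.0, plant_rank=16, seed=6)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def short_clip():
    """A 1.6-second random clip (just over one conv7 receptive field)."""
    return np.random.default_rng(9).standard_normal(36000).astype(np.float32)
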