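import numpy as np
import pytest

from voxelreuse import SimulationConfig, generate_dataset


@pytest.fixture
def make_dataset():
    """Factory for small simulated datasets with sensible test defaults."""

    def _make(n_subjects=1, grid_dims=(5, 4, 3), effect_size=1.5, noise_sd=1.0,
              shared_fraction=1.0, informative_fraction=0.1, seed=0, **kw):
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            grid_dims=grid_dims,
            effect_size=effect_size,
            noise_sd=noise_sd,
            shared_fraction=shared_fraction,
            informative_fraction=informative_fraction,
            rng_seed=seed,
            **kw,
        )
        return generate_dataset(cfg)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
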