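import numpy as np
import pytest

from dietscape import synthetic as syn


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic world shared across tests (deterministic)."""
    cfg = syn.WorldConfig(
        n_individuals=8,
        floodplain_count=4,
        n_taxa=40,
        n_days=21,
        fixes_per_day=12,
        min_samples=6,
        max_samples=9,
        depth_range=(8000, 15000),
        lidar_points_per_range=200,
    )
    return syn.generate_world(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
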