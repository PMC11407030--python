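import numpy as np
import pytest

from agetkit.model import TimeGrid
from agetkit.synthetic import (
    SyntheticConfig,
    default_ground_truth,
    forward_simulate_agets,
    generate_source_cloud,
    generate_tracks,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cells_per_cloud=400,
        n_source_clouds=3,
        n_tracks=40,
        n_frames=21,
        seed=42,
    )


@pytest.fixture(scope="session")
def source_cloud(small_config):
    return generate_source_cloud(small_config)


@pytest.fixture(scope="session")
def noiseless_cloud():
    cfg = SyntheticConfig(
        n_cells_per_cloud=500, n_tracks=10, expression_noise_sd=0.0, seed=5
    )
    return generate_source_cloud(cfg)


@pytest.fixture(scope="session")
def tracks(small_config):
    return generate_tracks(small_config)


@pytest.fixture(scope="session")
def grid(small_config) -> TimeGrid:
    return TimeGrid(n_frames=small_config.n_frames, total_span=1.0, substeps=10)


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def truth_agets(tracks, truth, grid):
    return forward_simulate_agets(tracks, truth, grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
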