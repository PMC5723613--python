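import numpy as np
import pytest

from divebout.simulate import SimConfig, simulate_bathymetry, simulate_trip


@pytest.fixture(scope="session")
def small_trip():
    """A small razorbill-like trip shared by read-only tests."""
    cfg = SimConfig(seed=11, n_bouts=4, dives_per_bout_mean=8)
    grid = simulate_bathymetry(cfg.grid_extent, cfg.grid_resolution, cfg.seed,
                               cfg.grid_depth_range)
    gps, depth, accel, truth = simulate_trip(cfg, grid)
    return cfg, grid, gps, depth, accel, truth


@pytest.fixture(scope="session")
def mixed_trip():
    """A small mixed benthic/pelagic trip shared by read-only tests."""
    cfg = SimConfig.guillemot_like(seed=7, n_bouts=4, dives_per_bout_mean=8)
    grid = simulate_bathymetry(cfg.grid_extent, cfg.grid_resolution, cfg.seed,
                               cfg.grid_depth_range)
    gps, depth, accel, truth = simulate_trip(cfg, grid)
    return cfg, grid, gps, depth, accel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
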