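import numpy as np
import pytest
from hypothesis import settings

from synprop.arena import build_spot_grid
from synprop.simulate import MEMORY_CD8, NAIVE_CD8, SimConfig, simulate_arena

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_grid():
    """The printed field layout: 10-um spots at 30-um pitch, 50,625 um^2."""
    return build_spot_grid(50_625.0, 10.0, 30.0, capacity=1)


@pytest.fixture(scope="session")
def memory_run():
    """A medium memory-cell arena run with ground truth, reused across tests."""
    grid = build_spot_grid(50_625.0 * 9, 10.0, 30.0, capacity=50)
    cfg = SimConfig(dt=0.5, duration=60.0, n_cells=300, seed=7)
    tracks, log = simulate_arena(grid, [MEMORY_CD8], cfg)
    return grid, cfg, tracks, log


@pytest.fixture(scope="session")
def naive_run():
    grid = build_spot_grid(50_625.0 * 9, 10.0, 30.0, capacity=50)
    cfg = SimConfig(dt=0.5, duration=60.0, n_cells=300, seed=7)
    tracks, log = simulate_arena(grid, [NAIVE_CD8], cfg)
    return grid, cfg, tracks, log


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
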