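import numpy as np
import pytest

from resghg import delineation as dl
from resghg import synthetic as syn


@pytest.fixture(scope="session")
def small_cfg():
    return syn.SyntheticConfig(seed=7, grid_size=(48, 48), n_dams=15)


@pytest.fixture(scope="session")
def small_landscape(small_cfg):
    return syn.synth_landscape(small_cfg)


@pytest.fixture(scope="session")
def small_fleet(small_cfg, small_landscape):
    return syn.synth_fleet(small_cfg, small_landscape)


@pytest.fixture(scope="session")
def tabular_fleet():
    cfg = syn.SyntheticConfig(seed=3)
    return syn.sample_fleet_records(cfg, n=120, seed=3)


def random_dem(rng, nr=None, nc=None):
    """A small conditioned DEM with a single outlet."""
    nr = nr or int(rng.integers(8, 25))
    nc = nc or int(rng.integers(8, 25))
    z = rng.normal(size=(nr, nc)).cumsum(axis=0) + rng.normal(size=(nr, nc))
    grid = dl.ElevationGrid(10.0 * z, cellsize=100.0)
    return dl.condition_dem(grid)


def brute_accumulation(d8):
    """Per-cell upstream counts by exhaustive per-cell downstream walks."""
    nr, nc = d8.shape
    acc = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if d8[r, c] == dl.NODATA:
                continue
            cur = (r, c)
            seen = set()
            while cur is not None and cur not in seen:
                acc[cur] += 1
                seen.add(cur)
                cur = dl.downstream_cell(cur[0], cur[1], d8)
    return acc
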