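import numpy as np
import pytest

from gapkit import BinaryRange, GridLayer, WorldConfig, make_world


@pytest.fixture
def equator_template():
    """5x5 grid of 0.4-degree cells straddling the equator.

    Center cell (2, 2) sits exactly at (0, 0); rook neighbours are about
    44.5 km away and diagonal neighbours about 62.9 km.
    """
    return GridLayer(np.zeros((5, 5)), origin_lon=-1.0, origin_lat=1.0, cell_size=0.4)


@pytest.fixture
def one_row_equator():
    """Single equatorial row of 100 equal-area cells (centers at lat 0)."""
    vals = np.ones((1, 100))
    return BinaryRange(vals, origin_lon=0.0, origin_lat=0.05, cell_size=0.1)


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale world shared by integration tests: 8 taxa, 40x40 grid."""
    cfg = WorldConfig(seed=11, n_taxa=8, n_rows=40, n_cols=40, n_env_layers=6,
                      n_occurrences=25, n_coordless=15)
    return make_world(cfg)


def random_distribution(rng, n):
    """Random probability vector, occasionally sparse."""
    p = rng.gamma(0.5, size=n)
    if rng.random() < 0.3:
        p[rng.random(n) < 0.5] = 0.0
    if p.sum() == 0:
        p[rng.integers(n)] = 1.0
    return p / p.sum()
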