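import pytest

from cwrgap import (
    load_genepool_registry,
    load_genepool_stats,
    load_range_change_table,
)
from cwrgap.grid import GridSpec
from cwrgap.synthetic import LayerSpec, make_env_stack


@pytest.fixture(scope="session")
def registry():
    return load_genepool_registry()


@pytest.fixture(scope="session")
def genepool_stats():
    return load_genepool_stats()


@pytest.fixture(scope="session")
def range_table():
    return load_range_change_table()


@pytest.fixture
def small_grid():
    return GridSpec(lon_min=0.0, lat_max=10.0, resolution=6.0, n_rows=20, n_cols=20)


@pytest.fixture
def small_env(small_grid):
    """Two quantized gradient layers (temperature-like and rain-like)."""
    env, _ = make_env_stack(
        small_grid,
        [
            LayerSpec("bio1", "col", 0.0, 20.0, quantize=0.5),
            LayerSpec("bio12", "row", 0.0, 1000.0, quantize=25.0),
        ],
        seed=0,
    )
    return env
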