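import numpy as np
import pytest

from nichepop.geo_core import EnvGrid, GridLayer
from nichepop.synthetic_data import SimConfig, gen_env_layers


def make_grid(values_by_name: dict[str, np.ndarray], mask: np.ndarray | None = None,
              xll: float = 0.0, yll: float = 0.0, cellsize: float = 1.0) -> EnvGrid:
    """Small EnvGrid from plain arrays (shared helper for hand-built fixtures)."""
    first = next(iter(values_by_name.values()))
    m = np.zeros_like(np.asarray(first, dtype=float), dtype=bool) if mask is None else mask
    return EnvGrid({
        name: GridLayer(np.asarray(v, dtype=float), m.copy(), xll, yll, cellsize)
        for name, v in values_by_name.items()
    })


@pytest.fixture
def small_env():
    """20x20, 3 autocorrelated standardized layers; deterministic."""
    env, _ = gen_env_layers(SimConfig(seed=7, grid_rows=20, grid_cols=20, n_layers=3))
    return env
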