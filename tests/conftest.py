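import numpy as np
import pytest

from dhidrought.grids import CompositeStack, GridSpec
from dhidrought.synthetic import SceneParams


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=12, x_origin=500000.0,
                    y_origin=5600000.0, x_size=300.0, y_size=300.0)


@pytest.fixture
def scene_params() -> SceneParams:
    """Compact default scene used across modules."""
    return SceneParams(n_rows=20, n_cols=20, seed=7)


def make_stack(values: np.ndarray, year: int = 2017,
               valid: np.ndarray | None = None) -> CompositeStack:
    """Stack from a [time, row, col] array with evenly spread dates."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    grid = GridSpec(n_rows=values.shape[1], n_cols=values.shape[2],
                    x_origin=0.0, y_origin=0.0, x_size=300.0, y_size=300.0)
    start = np.datetime64(f"{year}-01-05")
    dates = start + np.arange(n) * np.timedelta64(10, "D")
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return CompositeStack(values=values, valid=valid, dates=dates, grid=grid)
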