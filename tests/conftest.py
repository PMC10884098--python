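import numpy as np
import pandas as pd
import pytest

from axiscope.codes import LINE_TIER_CODE
from axiscope.regionality import classify_table, max_normalize, tier_table
from axiscope.simulate import BulkSimParams, simulate_bulk_profiles
from axiscope.types import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 3 cells with known detection fractions (2/3, 1/3, 1)."""
    return CountMatrix(
        genes=["gA", "gB", "gC"],
        cells=["c1", "c2", "c3"],
        X=np.array([[0, 1, 5], [2, 0, 0], [1, 1, 1]]),
    )


@pytest.fixture(scope="session")
def six_line_bulk() -> pd.DataFrame:
    """Noise-free duplicate bulk profiles realizing the six-line tier code."""
    return simulate_bulk_profiles(BulkSimParams(code=LINE_TIER_CODE, noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def six_line_calls(six_line_bulk):
    normalized, _ = max_normalize(six_line_bulk)
    return classify_table(tier_table(normalized))


def constant_tracks(
    velocity=(60.0, 0.0), n_cells=5, n_frames=5, interval_min=10.0, origin=(0.0, 0.0)
) -> pd.DataFrame:
    """Hand-built noise-free tracks under a constant velocity (µm/h)."""
    vx, vy = velocity
    rows = []
    for c in range(n_cells):
        x0, y0 = origin[0] + 30.0 * c, origin[1] + 17.0 * c
        for f in range(n_frames):
            t = f * interval_min
            rows.append(
                {
                    "cell_id": f"cell{c}",
                    "group": "SC",
                    "frame": f,
                    "t_min": t,
                    "x_um": x0 + vx * t / 60.0,
                    "y_um": y0 + vy * t / 60.0,
                }
            )
    return pd.DataFrame(rows)
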