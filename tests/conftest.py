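import numpy as np
import pytest

from rosettescreen.plate_imaging import (
    PlateImage,
    SegmentationParams,
    build_grid,
)
from rosettescreen.synthetic_data import default_layout, two_group_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """2×2 wells of 50 px pitch on a 100×100 image."""
    return {
        "n_rows": 2,
        "n_cols": 2,
        "pitch_y": 50,
        "pitch_x": 50,
        "image_height": 100,
        "image_width": 100,
    }


@pytest.fixture
def small_grid(small_layout):
    return build_grid(small_layout)


@pytest.fixture
def plate_layout():
    return default_layout()


@pytest.fixture
def gray_image():
    px = np.full((100, 100, 3), 128, dtype=np.uint8)
    return PlateImage(pixels=px, plate_id="p1", time_days=0.0)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def stress_scenario():
    """Primed vs unprimed at 75 mM plus the unstressed condition."""
    return two_group_scenario(condition=75, effect_multiplier=1.3, seed=7)


def rasterize_disk(center, radius):
    """Independent integer rasterization of a disk: all (y, x) with
    (y−cy)² + (x−cx)² ≤ r² — the oracle used against blob/mask counting."""
    cy, cx = center
    pts = []
    for y in range(int(cy - radius) - 1, int(cy + radius) + 2):
        for x in range(int(cx - radius) - 1, int(cx + radius) + 2):
            if (y - cy) ** 2 + (x - cx) ** 2 <= radius**2:
                pts.append((y, x))
    return pts
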