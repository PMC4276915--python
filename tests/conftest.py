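import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluorospot as fs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_point_spot(channel: str, row: float, col: float,
                    peak: float = 100.0) -> fs.Spot:
    """Minimal single-pixel spot at a subpixel center, for matching tests."""
    return fs.Spot(
        channel_id=channel, center_rc=(row, col), area_px=1,
        peak_intensity=peak, mean_intensity=peak,
        gradient_score=1.0, radial_cv=0.0,
        pixel_indices=np.array([[round(row), round(col)]]),
    )


def random_spot_sets(rng: np.random.Generator, channels, max_spots: int,
                     field: float = 100.0) -> dict:
    """Random point-spot sets, one list per channel."""
    out = {}
    for ch in channels:
        n = int(rng.integers(0, max_spots + 1))
        out[ch] = [
            make_point_spot(ch, *rng.uniform(1.0, field - 1.0, size=2))
            for _ in range(n)
        ]
    return out


@pytest.fixture(scope="session")
def small_well():
    """A modest simulated 3-channel well shared by read-only tests."""
    cfg = fs.SimulationConfig(image_shape=(256, 256), n_cells=15, seed=11)
    return fs.simulate_well(cfg)


@pytest.fixture()
def default_params():
    return fs.DetectionParams()
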