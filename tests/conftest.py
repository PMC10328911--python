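import numpy as np
import pytest

from maizemap import SimScenario, default_profiles, simulate_scene_stack
from maizemap.compositing import SceneStack


@pytest.fixture(scope="session")
def profiles():
    return default_profiles(seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A 40x40 simulated scene set shared by read-only tests."""
    scenario = SimScenario(grid_shape=(40, 40), seed=7)
    stack, truth, cropland, regions = simulate_scene_stack(
        scenario, default_profiles(seed=7))
    return {"scenario": scenario, "stack": stack, "truth": truth,
            "cropland": cropland, "regions": regions}


def make_stack(dates, data, cloud=None) -> SceneStack:
    """Build a toy SceneStack from (T, 6, H, W) float data."""
    data = np.asarray(data, np.float32)
    if cloud is None:
        cloud = np.zeros(data.shape, bool)
    return SceneStack(dates=list(dates), data=data, cloud=np.asarray(cloud, bool))


def random_toy_stack(rng, max_px=5, max_dates=8) -> SceneStack:
    """A random small stack with random cloud flags for oracle tests.

    Guarantees at least one scene per two-month compositing window.
    """
    from maizemap.calendar import DEFAULT_PERIODS

    h = int(rng.integers(1, max_px + 1))
    w = int(rng.integers(1, max_px + 1))
    dates = {int(rng.integers(lo, hi + 1)) for lo, hi in DEFAULT_PERIODS}
    n_extra = int(rng.integers(0, max_dates - len(dates) + 1))
    while len(dates) < 4 + n_extra:
        dates.add(int(rng.integers(91, 335)))
    dates = sorted(dates)
    t = len(dates)
    data = rng.random((t, 6, h, w)).astype(np.float32)
    cloud = rng.random((t, 6, h, w)) < rng.uniform(0.0, 0.5)
    return make_stack(dates, data, cloud)
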