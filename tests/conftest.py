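import numpy as np
import pytest

from deltarad.images import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_phantom(shape, seed=0, n_levels=4):
    """Small integer-valued volume with an all-true mask, for oracle tests."""
    r = np.random.default_rng(seed)
    vol = ImageVolume(r.integers(0, n_levels, size=shape).astype(float))
    mask = RoiMask(np.ones(shape, dtype=bool))
    return vol, mask


def make_sphere_mask(shape, radius, center=None):
    if center is None:
        center = [(n - 1) / 2 for n in shape]
    grids = np.indices(shape)
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return RoiMask(q <= radius**2)


@pytest.fixture
def phantom_4():
    return make_phantom((4, 4, 4), seed=3)


@pytest.fixture
def outcomes_frame():
    """Deterministic 20-subject censored survival table."""
    import pandas as pd

    r = np.random.default_rng(7)
    time = r.exponential(300, size=20).round(1) + 1
    event = r.integers(0, 2, size=20)
    event[:4] = 1  # guarantee events
    return pd.DataFrame({"time_days": time, "event": event})
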