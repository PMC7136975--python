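import numpy as np
import pytest

from gradscape.raster import Raster
from gradscape.sites import SiteSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sites17(rng):
    """17 well-spread sites on a 10 km square (the study's pair universe size)."""
    pts = []
    r = np.random.default_rng(99)
    while len(pts) < 17:
        p = r.uniform(500, 9500, 2)
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= 1500 for q in pts):
            pts.append(p)
    arr = np.array(pts)
    return SiteSet([f"S{i + 1:02d}" for i in range(17)], arr[:, 0], arr[:, 1])


@pytest.fixture
def small_raster():
    vals = np.arange(25, dtype=float).reshape(5, 5)
    return Raster(vals, cell_size=10.0, origin=(0.0, 50.0))
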