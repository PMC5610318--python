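import logging

import numpy as np
import pytest
from hypothesis import settings

import paintcluster as pc

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

# the fov-rectangle fallback warning is expected noise in most tests
logging.getLogger("paintcluster.cluster").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Small, fast scene: ~100 clusters, a few thousand localizations."""
    return pc.SceneConfig(
        fov_width=4000.0,
        fov_height=4000.0,
        receptors_per_channel=118.0,  # keeps base hosting probability ~0.5
        n_fiducials=3,
        seed=7,
    )


@pytest.fixture
def two_blob_table():
    """Two tight localization blobs 500 nm apart, single channel."""
    rng = np.random.default_rng(3)
    a = rng.normal([1000.0, 1000.0], 5.0, (40, 2))
    b = rng.normal([1500.0, 1000.0], 5.0, (40, 2))
    pts = np.vstack([a, b])
    table = pc.LocalizationTable.from_arrays(
        frame=np.zeros(len(pts), int),
        x=pts[:, 0],
        y=pts[:, 1],
        channel=["EGFR"] * len(pts),
        fov=(2500.0, 2000.0),
        n_frames=1,
    )
    truth_labels = np.array([0] * 40 + [1] * 40)
    return table, truth_labels
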