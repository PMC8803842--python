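import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupretrieval.pose_io import ANIMALS, PART_NAMES, PoseTrack
from pupretrieval.roi import Circle, ROIConfig
from pupretrieval.synthetic import DAM_TEMPLATE, PUP_TEMPLATE

settings.register_profile(
    "default", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

BODY_PARTS = [(a, p) for a in ANIMALS for p in PART_NAMES]


def build_track(n_frames=20, fps=10.0, dam_center=(200.0, 200.0),
                pup_center=(600.0, 400.0), jitter=0.0, seed=0,
                unit="px", likelihood=1.0):
    """Stationary two-animal track from the rigid body templates."""
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, 14, 3))
    coords[:, :7, :2] = np.asarray(dam_center) + DAM_TEMPLATE
    coords[:, 7:, :2] = np.asarray(pup_center) + PUP_TEMPLATE
    if jitter > 0:
        coords[:, :, :2] += rng.normal(0, jitter, (n_frames, 14, 2))
    coords[:, :, 2] = likelihood
    return PoseTrack(coords, list(BODY_PARTS), fps=fps, unit=unit)


@pytest.fixture
def make_track():
    return build_track


@pytest.fixture
def square_roi():
    """Unit-friendly ROI: 100px square nest with a core circle inside."""
    return ROIConfig(
        nest=np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]]),
        core_nest=Circle(np.array([50.0, 50.0]), 20.0))
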