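import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flychain import synthscene as ss
from flychain import tracking as tr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

CHAMBER = (83, 417)


@pytest.fixture
def chamber_shape():
    return CHAMBER


@pytest.fixture
def fly_factory():
    """Render a single fly and return (silhouette, true_pose, mask)."""

    def make(position=(41.0, 60.0), heading=0.0, shape=None):
        shape = shape or ss.FlyShape()
        mask = ss.render_fly(position, heading, shape, CHAMBER)
        sil = tr.Silhouette(pixels=np.argwhere(mask))
        true = ss.TruePose(position=np.asarray(position, float), heading_rad=heading, shape=shape)
        return sil, true, mask

    return make


@pytest.fixture
def random_single_fly_frames():
    """200 rendered single-fly frames with uniform random pose."""
    rng = np.random.default_rng(0)
    out = []
    for _ in range(200):
        pos = (rng.uniform(15, 68), rng.uniform(15, 400))
        th = rng.uniform(0, 2 * math.pi)
        mask = ss.render_fly(pos, th, ss.FlyShape(), CHAMBER)
        out.append((np.asarray(pos), th, mask))
    return out
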