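import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neutraltrack import template_landmarks
from neutraltrack.synthetic_data import project_to_2d


@pytest.fixture
def template():
    """The fixed mirror-symmetric 3-D landmark template."""
    return template_landmarks()


@pytest.fixture
def template_2d(template):
    """Exact mid-sagittal projection of the template."""
    return project_to_2d(template)


def random_rigid_motion(rng, scale_range=(1.0, 1.0)):
    """Random rotation + translation (+ optional uniform scaling) as a callable."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-100.0, 100.0, size=3)
    s = float(rng.uniform(*scale_range))

    def move(p):
        return s * (R @ np.asarray(p, dtype=float)) + t

    return move


@pytest.fixture
def rigid_motion_factory():
    return random_rigid_motion
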