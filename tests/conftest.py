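import numpy as np
import pytest

from tipshape.pf_geometry import ResampledTrace


def circle_arc_points(radius: float, step: float, sweep: float = np.pi / 2,
                      z: float = 0.0) -> np.ndarray:
    """Equal-arc samples of a planar circular arc (equal chords)."""
    theta = np.arange(0.0, sweep, step / radius)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.full_like(theta, z)])


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-100, 100, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def circle_trace():
    """Quarter circle, R = 20 nm, equal chords at 2 nm arc spacing."""
    return ResampledTrace(points=circle_arc_points(20.0, 2.0), step=2.0)
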