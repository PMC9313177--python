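import numpy as np
import pytest

from shapemsm.trajectory_io import StructureFrame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_frame():
    """A 5-atom frame with a CA atom, small enough to check by hand."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
            [0.0, 0.0, 3.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return StructureFrame(coords, ("N", "CA", "C", "O", "CB"))


@pytest.fixture
def toy_trajectory(rng):
    """10 frames of 6 atoms saved every 2 ps."""
    names = ("N", "CA", "C", "O", "CA", "CB")
    frames = [StructureFrame(rng.normal(size=(6, 3), scale=3.0), names) for _ in range(10)]
    return Trajectory(frames, frame_interval=2.0, trajectory_id="toy")


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans
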