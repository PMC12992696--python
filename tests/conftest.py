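import numpy as np
import pytest

from gpcrswitch.synthetic import base_scaffold
from gpcrswitch.trajectory import Atom, Frame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def scaffold_trajectory(coord_frames) -> tuple[Trajectory, object]:
    """Build a Trajectory from explicit (n_atoms, 3) coordinate arrays
    laid over the synthetic scaffold topology."""
    sc, rmap = base_scaffold()
    frames = []
    for i, coords in enumerate(coord_frames):
        atoms = [Atom(j + 1, nm, rn, rnum, ch, el, coords[j])
                 for j, (nm, rn, rnum, ch, el) in enumerate(sc.names)]
        frames.append(Frame(i, float(i), atoms))
    return Trajectory(frames), rmap


@pytest.fixture
def scaffold():
    """(scaffold, residue map) in base geometry."""
    return base_scaffold()


@pytest.fixture
def base_trajectory(scaffold):
    sc, _ = scaffold
    traj, rmap = scaffold_trajectory([sc.base()])
    return traj, rmap, sc


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-10, 10, size=3)
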