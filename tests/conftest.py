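import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from memprobe import (
    Particle, Selection, Species, SyntheticSpec, Trajectory, gen_bilayer,
)


@pytest.fixture
def small_bilayer():
    """40-lipid bilayer, 51 frames, fixed seed — cheap all-purpose fixture."""
    spec = SyntheticSpec(n_lipids_per_leaflet=20, box_xy=40.0, n_frames=51,
                         dt=0.1, seed=11)
    traj, truth = gen_bilayer(spec)
    return traj, truth, spec


@pytest.fixture
def p_selection():
    return Selection(role="P")


def make_static_trajectory(coords, box=(100.0, 100.0, 100.0), n_frames=1,
                           species=Species.ION, role="ion", charges=None,
                           times=None):
    """Trajectory with given per-particle coords repeated over frames."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    parts = [Particle(i, species, role, lipid_id=i,
                      charge=0.0 if charges is None else charges[i])
             for i in range(n)]
    c = np.broadcast_to(coords, (n_frames, n, 3)).copy()
    t = np.arange(n_frames, dtype=float) if times is None else np.asarray(times)
    return Trajectory(parts, c, t, np.asarray(box, dtype=float))
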