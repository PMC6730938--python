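import numpy as np
import pytest

import nucleomix as nm


def make_trajectory(positions, save_interval=0.1, nucleolar=None, mu=0.1):
    """Wrap a (T, N, 3) position array in a Trajectory for analysis tests."""
    positions = np.asarray(positions, dtype=float)
    T, N, _ = positions.shape
    if nucleolar is None:
        nucleolar = np.ones(N, dtype=bool)
    topo = nm.GenomeTopology(
        n_beads=N, chains=[(0, N - 1, None, None)],
        nucleolar_mask=nucleolar)
    params = nm.SimParams(mu=mu, total_time=(T - 1) * save_interval,
                          save_interval=save_interval)
    times = np.arange(T) * save_interval
    return nm.Trajectory(times, positions, topo, params,
                         link_log=np.empty((0, 4)))


@pytest.fixture
def scripted_trajectory():
    """4 beads with hand-scripted motions: pair (0,1) oscillates in and out
    of contact; beads 2, 3 stay far from everything."""
    T = 6
    pos = np.zeros((T, 4, 3))
    # bead 0 fixed at origin; bead 1 moves along x
    x1 = [50, 50, 400, 400, 400, 60]
    for t in range(T):
        pos[t, 1, 0] = x1[t]
    pos[:, 2, 1] = 2000.0
    pos[:, 3, 2] = 4000.0
    return make_trajectory(pos)


@pytest.fixture(scope="session")
def short_sim():
    """One short but real simulation shared across contract tests."""
    topo = nm.nucleolus_preset(40)
    params = nm.SimParams(mu=0.09, total_time=5.0, seed=123,
                          nucleus_radius=400.0)
    return nm.simulate(topo, params)
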