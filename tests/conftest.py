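import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dsbsim as ds

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_topology() -> ds.Topology:
    """Three 33-residue gluten-like chains with a couple of cysteines."""
    return ds.Topology(["QQPGQCAQSTQ" * 3] * 3)


@pytest.fixture(scope="session")
def saw_state(small_topology):
    """A dilute SAW start shared (read-only) by force-field tests."""
    return ds.init_saw(small_topology, 0.05, seed=1)


@pytest.fixture(scope="session")
def forcefield(small_topology) -> ds.ForceField:
    return ds.ForceField(small_topology)


def fd_force_check(ff, positions, box, registry=None, stride=3, h=1e-5,
                   wall_on=False):
    """Central-difference gradient check; returns worst error / ||F||_max."""
    e, f = ff.energy_forces(positions, box, registry=registry,
                            wall_on=wall_on)
    fmax = np.abs(f).max()
    worst = 0.0
    for i in range(0, positions.shape[0], stride):
        for k in range(3):
            p1 = positions.copy()
            p1[i, k] += h
            p2 = positions.copy()
            p2[i, k] -= h
            e1 = ff.energy_forces(p1, box, registry=registry,
                                  wall_on=wall_on)[0].total
            e2 = ff.energy_forces(p2, box, registry=registry,
                                  wall_on=wall_on)[0].total
            worst = max(worst, abs(-(e1 - e2) / (2 * h) - f[i, k]))
    return worst / max(fmax, 1e-12)
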