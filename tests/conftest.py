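"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically (no stored data); fixtures are
session-scoped where the objects are immutable and expensive.
"""

import numpy as np
import pytest

import porescope as ps


@pytest.fixture(scope="session")
def subunits():
    return ps.toy_subunit_map()


@pytest.fixture(scope="session")
def cylinder_channel():
    """Constant-radius pore, R = 2.3 Å (so the gate diameter scale is 4.6 Å)."""
    spec = ps.SyntheticSpec(seed=11, pore_radius_function=ps.cylinder(2.3))
    structure, truth = ps.make_toy_channel(spec)
    return structure, truth


@pytest.fixture(scope="session")
def hourglass_channel():
    """Hourglass pore: 6 Å at the ends, analytic 2 Å waist at the 9′ level."""
    spec = ps.SyntheticSpec(
        seed=12, pore_radius_function=ps.hourglass(6.0, 2.0, 13.5, width=8.0))
    structure, truth = ps.make_toy_channel(spec)
    return structure, truth


@pytest.fixture(scope="session")
def contact_trajectory():
    """Wide-pore trajectory with programmed contacts, waters and ligand drift."""
    n = 20
    spec = ps.SyntheticSpec(
        seed=21, n_frames=n,
        pore_radius_function=ps.cylinder(6.0),
        ligand_drift=0.1,
        contact_schedule={("A", 257): 1.0, ("B", 252): 0.3},
        water_plan=[3, 5] * (n // 2),
    )
    traj, truth = ps.make_toy_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def breathing_trajectory():
    """ECD ring scaled radially by a programmed per-frame factor."""
    n = 12
    factors = np.concatenate([np.ones(4), np.full(4, 1.1), np.full(4, 0.95)])
    spec = ps.SyntheticSpec(
        seed=22, n_frames=n,
        pore_radius_function=ps.cylinder(6.0),
        breathing=factors,
    )
    traj, truth = ps.make_toy_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def toy_ecd_ranges():
    """Residue ranges matching the generator's pseudo upper-ECD block."""
    lo, hi = ps.synthdata.ECD_RESIDUES[0], ps.synthdata.ECD_RESIDUES[-1]
    return ps.EcdRanges(ranges={c: [(lo, hi)] for c in ("alpha", "beta", "gamma")})


@pytest.fixture()
def two_pose_trajectory():
    """Two ligand pose groups 5 Å apart with 0.2 Å jitter; ground-truth labels."""
    n = 24
    spec = ps.SyntheticSpec(seed=31, n_frames=n,
                            pore_radius_function=ps.cylinder(6.0))
    traj, _ = ps.make_toy_trajectory(spec)
    rng = np.random.default_rng(31)
    lig_idx = ps.select(traj.topology, "resname DHS").indices
    frames = traj.frames.copy()
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    for t in range(n):
        offset = np.array([5.0, 0.0, 0.0]) * labels[t]
        frames[t][lig_idx] += offset + rng.normal(0.0, 0.2 / np.sqrt(3), 3)
    traj = ps.Trajectory(topology=traj.topology, frames=frames)
    return traj, labels
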