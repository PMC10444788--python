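"""Structure/trajectory I/O, prime numbering, superposition and axis alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import porescope as ps
from porescope.structio import _kabsch


MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C
ATOM      3  CB AALA A   1       1.000   0.000   0.000  0.50 10.00           C
ATOM      4  CB BALA A   1       2.000   0.000   0.000  0.50 10.00           C
ATOM      5  N   ALA A   2       0.000   3.000   0.000  1.00 10.00           N
END
"""


class TestReadWrite:
    def test_minimal_single_atom_parse(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        s = ps.read_structure(p)
        assert s.n_atoms == 1
        assert s.chain_ids[0] == "A" and s.atom_names[0] == "CA"
        np.testing.assert_allclose(s.coords[0], [11.104, 13.207, 2.100])

    def test_structure_roundtrip_pdb_precision(self, tmp_path, cylinder_channel):
        structure, _ = cylinder_channel
        p = tmp_path / "chan.pdb"
        ps.write_structure(structure, p)
        back = ps.read_structure(p)
        assert back.n_atoms == structure.n_atoms
        assert (back.chain_ids == structure.chain_ids).all()
        assert (back.res_numbers == structure.res_numbers).all()
        assert (back.atom_names == structure.atom_names).all()
        assert np.abs(back.coords - structure.coords).max() < 1e-3

    def test_altloc_keeps_highest_occupancy_ties_alphabetical(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = ps.read_structure(p)
        # CA: B wins on occupancy; CB: tie at 0.5 -> A wins alphabetically
        ca = s.coords[s.atom_names == "CA"][0]
        cb = s.coords[s.atom_names == "CB"][0]
        assert ca[0] == pytest.approx(5.0)
        assert cb[0] == pytest.approx(1.0)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        p = tmp_path / "junk.cif"
        p.write_text("this is not a coordinate file\n")
        with pytest.raises((ps.FormatError, FileNotFoundError, Exception)):
            s = ps.read_structure(p, format="mmcif")
            assert s.n_atoms  # must not silently return something

    def test_empty_model_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ps.FormatError):
            ps.read_structure(p)


class TestTrajectoryIO:
    def test_multimodel_frame_count_and_default_interval(self, tmp_path,
                                                         contact_trajectory):
        traj, _ = contact_trajectory
        p = tmp_path / "traj.pdb"
        ps.write_trajectory(traj, p)
        back = ps.read_trajectory(p)
        assert back.n_frames == traj.n_frames
        assert back.frame_interval == 0.4
        assert np.abs(back.frames - traj.frames).max() < 1e-3

    def test_known_per_frame_translation_recovered(self, tmp_path):
        spec = ps.SyntheticSpec(seed=7, n_frames=5, ligand_drift=0.25,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_toy_trajectory(spec)
        p = tmp_path / "drift.pdb"
        ps.write_trajectory(traj, p)
        back = ps.read_trajectory(p)
        lig = ps.select(back.topology, "resname DHS")
        com_z = back.frames[:, lig.indices, 2].mean(axis=1)
        np.testing.assert_allclose(com_z - com_z[0], 0.25 * np.arange(5),
                                   atol=2e-3)

    def test_model_atom_count_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00 10.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ENDMDL\nEND\n")
        with pytest.raises(ps.FormatError):
            ps.read_trajectory(p)


class TestPrimeMap:
    def test_shipped_anchor_arithmetic(self, cylinder_channel, subunits):
        structure, _ = cylinder_channel
        pm = ps.build_prime_map(structure, subunits)
        assert pm.residue_number("alpha", 2) == 257   # αV257
        assert pm.residue_number("beta", 2) == 252    # βA252
        assert pm.residue_number("beta", -2) == 248
        assert pm.residue_number("alpha", 9) == 264   # anchor itself
        assert pm.residue_number("gamma", 20) == 285

    @settings(max_examples=100, derandomize=True)
    @given(k=st.integers(-2, 20), j=st.integers(-2, 20))
    def test_prime_arithmetic_offsets(self, k, j):
        pm = ps.PrimeMap(anchors=dict(ps.DEFAULT_PRIME_ANCHORS))
        for cls in ("alpha", "beta", "gamma"):
            assert (pm.residue_number(cls, k) - pm.residue_number(cls, j)) == k - j

    def test_missing_anchor_raises(self, cylinder_channel, subunits):
        structure, _ = cylinder_channel
        with pytest.raises(ps.SelectionError):
            ps.build_prime_map(structure, subunits,
                               anchors={"alpha": 999, "beta": 259, "gamma": 274})

    def test_non_leucine_anchor_warns_not_fatal(self, cylinder_channel, subunits):
        structure, _ = cylinder_channel
        # point the alpha anchor at the 2' valine ring: present but not LEU
        with pytest.warns(UserWarning, match="not LEU"):
            pm = ps.build_prime_map(
                structure, subunits,
                anchors={"alpha": 257, "beta": 259, "gamma": 274})
        assert pm.residue_number("alpha", 9) == 257


class TestSuperposition:
    def test_identical_structures_zero_rmsd_identity(self, cylinder_channel):
        structure, _ = cylinder_channel
        tr, rmsd = ps.superpose(structure, structure)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-8)

    def test_rotated_translated_copy_recovered(self, cylinder_channel):
        structure, _ = cylinder_channel
        R = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        moved = structure.with_coords(structure.coords @ R.T + [4.0, -2.0, 9.0])
        tr, rmsd = ps.superpose(moved, structure)
        assert rmsd < 1e-6
        np.testing.assert_allclose(
            tr.apply(moved.coords), structure.coords, atol=1e-6)

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, r_ab = _kabsch(a, b)
        _, r_ba = _kabsch(b, a)
        assert abs(r_ab - r_ba) < 1e-9

    def test_matches_bruteforce_rotation_optimizer(self):
        """Kabsch result equals direct minimisation over rotation vectors."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, rmsd = _kabsch(a, b)
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)

            def resid(v):
                Rm = Rotation.from_rotvec(v).as_matrix()
                return np.sqrt(((ac @ Rm.T - bc) ** 2).sum(axis=1).mean())

            best = min(
                minimize(resid, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 5000}).fun
                for x0 in [np.zeros(3), np.array([3.0, 0, 0]),
                           np.array([0, 3.0, 0]), np.array([0, 0, 3.0]),
                           np.array([1.8, 1.8, 1.8])])
            assert rmsd <= best + 1e-6
            assert abs(rmsd - best) < 1e-4

    def test_too_few_or_collinear_pairs_raise(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        s = ps.synthdata._assemble(["A"] * 5, list(range(1, 6)), ["GLY"] * 5,
                                   ["CA"] * 5, line.tolist())
        with pytest.raises(ps.GeometryError):
            ps.superpose(s, s, (ps.Selection(indices=np.array([0, 1])),
                                ps.Selection(indices=np.array([0, 1]))))
        with pytest.raises(ps.GeometryError):
            ps.superpose(s, s)


class TestAxisAlignment:
    def test_channel_built_along_z_aligns_to_identity(self, cylinder_channel,
                                                      subunits):
        structure, truth = cylinder_channel
        aligned, axis = ps.align_pore_axis(structure, subunits,
                                           prime_map=truth["prime_map"])
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-6)
        # only a z-translation to the M2 centroid should remain
        d = aligned.coords - structure.coords
        assert np.abs(d[:, :2]).max() < 1e-6

    def test_known_rotation_recovered_within_half_degree(self, cylinder_channel,
                                                         subunits):
        structure, truth = cylinder_channel
        R = Rotation.from_rotvec([0.5, -0.2, 0.9]).as_matrix()
        moved = structure.with_coords(structure.coords @ R.T + [10.0, 5.0, -3.0])
        _, axis = ps.align_pore_axis(moved, subunits,
                                     prime_map=truth["prime_map"])
        true_axis = R @ np.array([0.0, 0.0, 1.0])
        angle = np.degrees(np.arccos(np.clip(abs(axis.direction @ true_axis),
                                             -1, 1)))
        assert angle < 0.5

    def test_idempotent(self, cylinder_channel, subunits):
        structure, truth = cylinder_channel
        once, _ = ps.align_pore_axis(structure, subunits,
                                     prime_map=truth["prime_map"])
        twice, _ = ps.align_pore_axis(once, subunits,
                                      prime_map=truth["prime_map"])
        assert np.abs(twice.coords - once.coords).max() < 1e-6

    def test_non_pentamer_raises(self):
        with pytest.raises(ps.GeometryError):
            ps.SubunitMap(chain_to_class={"A": "alpha", "B": "beta"})


class TestSelections:
    def test_compound_expression(self, contact_trajectory):
        traj, _ = contact_trajectory
        sel = ps.select(traj.topology, "chain A and resnum 253-275 and heavy")
        assert len(sel) > 0
        assert set(traj.topology.chain_ids[sel.indices]) == {"A"}

    def test_empty_selection_raises(self, contact_trajectory):
        traj, _ = contact_trajectory
        with pytest.raises(ps.SelectionError):
            ps.select(traj.topology, "resname XYZ")
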