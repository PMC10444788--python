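"""Ligand rmsd/z traces, the crop rule, and quality-threshold pose clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import porescope as ps


def _selections(traj):
    lig = ps.select(traj.topology, "resname DHS and heavy")
    ali = ps.select(traj.topology, "protein and name CA")
    return lig, ali


def _static_traj(n=8, seed=41):
    spec = ps.SyntheticSpec(seed=seed, n_frames=n,
                            pore_radius_function=ps.cylinder(6.0))
    return ps.make_toy_trajectory(spec)[0]


class TestRmsdTrace:
    def test_static_ligand_all_zeros(self):
        traj = _static_traj()
        trace = ps.ligand_rmsd_trace(traj, *_selections(traj))
        np.testing.assert_allclose(trace.rmsd, 0.0, atol=1e-9)
        assert not trace.cropped.any()

    def test_single_frame_translation_gives_exact_rmsd(self):
        traj = _static_traj()
        lig, ali = _selections(traj)
        frames = traj.frames.copy()
        frames[3][lig.indices] += np.array([3.0, 0.0, 4.0])  # |d| = 5
        traj = ps.Trajectory(topology=traj.topology, frames=frames)
        trace = ps.ligand_rmsd_trace(traj, lig, ali)
        assert trace.rmsd[3] == pytest.approx(5.0, abs=1e-9)
        assert np.abs(np.delete(trace.rmsd, 3)).max() < 1e-9

    def test_programmed_jitter_matches_ground_truth(self):
        spec = ps.SyntheticSpec(seed=43, n_frames=30, ligand_jitter_sigma=0.4,
                                pore_radius_function=ps.cylinder(6.0))
        traj, truth = ps.make_toy_trajectory(spec)
        trace = ps.ligand_rmsd_trace(traj, *_selections(traj))
        np.testing.assert_allclose(trace.rmsd, truth["ligand_rmsd"], atol=1e-9)

    def test_crop_rule_stores_crop_value_and_flag(self):
        spec = ps.SyntheticSpec(seed=44, n_frames=20, escape_frame=10,
                                escape_speed=8.0,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_unbinding_trajectory(spec)
        lig, ali = _selections(traj)
        thr, val = ps.CROP_PRESET_UNBINDING
        trace = ps.ligand_rmsd_trace(traj, lig, ali,
                                     crop_threshold=thr, crop_value=val)
        assert trace.cropped.any()
        assert (trace.rmsd[trace.cropped] == val).all()
        assert (trace.raw_rmsd[trace.cropped] > thr).all()
        # crop flags only after the escape
        assert trace.cropped[:10].sum() == 0

    def test_rigid_transform_of_every_frame_leaves_trace_unchanged(self):
        spec = ps.SyntheticSpec(seed=45, n_frames=10, ligand_jitter_sigma=0.3,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_toy_trajectory(spec)
        lig, ali = _selections(traj)
        base = ps.ligand_rmsd_trace(traj, lig, ali)
        R = Rotation.from_rotvec([0.2, 0.5, -0.4]).as_matrix()
        moved = ps.Trajectory(topology=traj.topology,
                              frames=traj.frames @ R.T + np.array([3.0, -7.0, 1.0]))
        trace = ps.ligand_rmsd_trace(moved, lig, ali)
        np.testing.assert_allclose(trace.rmsd, base.rmsd, atol=1e-6)


class TestZTrace:
    def test_static_ligand_zero_and_frame0_anchored(self):
        traj = _static_traj()
        zt = ps.ligand_z_trace(traj, *_selections(traj))
        assert zt.dz[0] == 0.0
        np.testing.assert_allclose(zt.dz, 0.0, atol=1e-9)

    def test_programmed_drift_accumulates(self):
        spec = ps.SyntheticSpec(seed=46, n_frames=51, ligand_drift=0.1,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_toy_trajectory(spec)
        zt = ps.ligand_z_trace(traj, *_selections(traj))
        assert zt.dz[50] == pytest.approx(5.0, abs=1e-6)

    def test_sulfate_down_drift_toward_inner_leaflet_is_negative_slope(self):
        # pose programmed to slip toward the intracellular side (-z)
        spec = ps.SyntheticSpec(seed=47, n_frames=40, ligand_drift=-0.05,
                                ligand_jitter_sigma=0.2,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_toy_trajectory(spec)
        zt = ps.ligand_z_trace(traj, *_selections(traj))
        assert zt.slope_per_frame() < 0


class TestClustering:
    def test_identical_frames_single_cluster(self):
        traj = _static_traj(n=6)
        res = ps.cluster_poses(traj, *_selections(traj))
        assert res.n_clusters == 1
        assert res.populations.tolist() == [6]
        assert (res.labels == 0).all()

    def test_two_separated_groups_exact_membership(self, two_pose_trajectory):
        traj, labels = two_pose_trajectory
        res = ps.cluster_poses(traj, *_selections(traj), cutoff=1.0)
        assert res.n_clusters == 2
        # same partition as ground truth (cluster ids may swap)
        got = res.labels
        same = ((got == got[0]) == (labels == labels[0])).all()
        assert same
        # brute-force check: every within-cluster pair under cutoff spans the
        # full pairwise matrix partition
        d = ps.pairwise_rmsd_matrix(traj, *_selections(traj))
        for c in range(2):
            members = np.flatnonzero(got == c)
            assert (d[np.ix_(members, members)] <= 1.0).all()
        assert d[np.ix_(got == 0, got == 1)].min() > 1.0

    def test_populations_non_increasing_and_representatives_members(self,
                                                                    two_pose_trajectory):
        traj, _ = two_pose_trajectory
        res = ps.cluster_poses(traj, *_selections(traj), cutoff=1.0)
        assert (np.diff(res.populations) <= 0).all()
        for cid, rep in enumerate(res.representatives):
            assert res.labels[rep] == cid

    def test_permutation_stability(self, two_pose_trajectory):
        traj, _ = two_pose_trajectory
        lig, ali = _selections(traj)
        res = ps.cluster_poses(traj, lig, ali, cutoff=1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        # keep frame 0 first so the reference pose is unchanged
        perm = np.concatenate([[0], perm[perm != 0]])
        shuffled = ps.Trajectory(topology=traj.topology,
                                 frames=traj.frames[perm])
        res2 = ps.cluster_poses(shuffled, lig, ali, cutoff=1.0)
        unshuffled = np.empty_like(res2.labels)
        unshuffled[perm] = res2.labels
        a, b = res.labels, unshuffled
        assert ((a[:, None] == a[None, :]) == (b[:, None] == b[None, :])).all()

    def test_top_five_representatives_from_ten_cluster_run(self):
        # 6 well-separated pose groups of descending size
        sizes = [8, 6, 5, 3, 2, 1]
        n = sum(sizes)
        spec = ps.SyntheticSpec(seed=48, n_frames=n,
                                pore_radius_function=ps.cylinder(6.0))
        traj, _ = ps.make_toy_trajectory(spec)
        lig = ps.select(traj.topology, "resname DHS")
        frames = traj.frames.copy()
        t = 0
        for g, size in enumerate(sizes):
            for _ in range(size):
                frames[t][lig.indices] += np.array([4.0 * g, 0.0, 0.0])
                t += 1
        traj = ps.Trajectory(topology=traj.topology, frames=frames)
        res = ps.cluster_poses(traj, ps.select(traj.topology, "resname DHS and heavy"),
                               ps.select(traj.topology, "protein and name CA"),
                               cutoff=1.0, max_clusters=10)
        assert res.n_clusters == 6
        assert res.populations.tolist() == sizes
        top5 = res.top_representatives(5)
        assert len(top5) == 5
        assert (res.labels[top5] == np.arange(5)).all()

    def test_invalid_cutoff_raises(self):
        traj = _static_traj(n=4)
        with pytest.raises(ValueError):
            ps.cluster_poses(traj, *_selections(traj), cutoff=0.0)
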