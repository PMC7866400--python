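import numpy as np
import pytest

from thermostruct import synthetic_data as synth
from thermostruct import trajectory_analysis as ta

import oracles
from conftest import random_rotation


@pytest.fixture(scope="module")
def small_ref():
    return synth.build_ideal_peptide("AKEAVADLAKEA")


@pytest.fixture(scope="module")
def noisy_traj(small_ref):
    traj, _ = synth.fluctuation_trajectory(small_ref, 0.05, 40, seed=7)
    return traj


class TestReadWrite:
    def test_multi_model_roundtrip(self, noisy_traj):
        text = ta.write_trajectory_pdb(noisy_traj)
        back = ta.read_trajectory(text, "pdb")
        assert back.n_frames == noisy_traj.n_frames
        assert back.n_atoms == noisy_traj.n_atoms
        assert np.allclose(back.frames, noisy_traj.frames, atol=1.5e-3)

    def test_three_model_shapes(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.01, 3, seed=1)
        back = ta.read_trajectory(ta.write_trajectory_pdb(traj), "pdb")
        assert back.n_frames == 3
        assert back.n_atoms == small_ref.n_atoms

    def test_xyz_roundtrip(self, noisy_traj):
        text = ta.write_xyz(noisy_traj)
        back = ta.read_trajectory(text, "xyz", topology=noisy_traj.topology)
        assert np.allclose(back.frames, noisy_traj.frames, atol=1e-5)

    def test_atom_count_mismatch_names_frame(self, small_ref, noisy_traj):
        text = ta.write_xyz(noisy_traj)
        wrong = synth.build_ideal_peptide("AK")
        with pytest.raises(ta.TrajectoryFormatError, match="frame 0"):
            ta.read_trajectory(text, "xyz", topology=wrong)

    def test_zero_frames_rejected(self, small_ref):
        with pytest.raises(ta.TrajectoryFormatError):
            ta.read_trajectory("", "xyz", topology=small_ref)


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        X = rng.normal(size=(10, 3))
        R, t, rmsd = ta.kabsch_fit(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_removes_rigid_motion(self, rng):
        X = rng.normal(size=(10, 3))
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        Y = X @ Rz.T + np.array([3.0, -1.0, 7.0])
        _, _, rmsd = ta.kabsch_fit(Y, X)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors_oracle(self, rng):
        from scipy.spatial.transform import Rotation
        for _ in range(5):
            X = rng.normal(size=(12, 3))
            Y = rng.normal(size=(12, 3))
            _, _, rmsd = ta.kabsch_fit(X, Y)
            # independent oracle: scipy's rotational alignment on centered sets
            Xc, Yc = X - X.mean(0), Y - Y.mean(0)
            rot, _ = Rotation.align_vectors(Yc, Xc)
            ref = np.sqrt(np.mean(np.sum((rot.apply(Xc) - Yc) ** 2, axis=1)))
            assert rmsd == pytest.approx(ref, abs=1e-6)
            # fitted rmsd never exceeds the unfitted one
            raw = np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1)))
            assert rmsd <= raw + 1e-9

    def test_collinear_points_rejected(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            ta.kabsch_fit(X, X * 2.0)


class TestSeries:
    def test_identical_frames_zero_rmsd(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.0, 5, seed=0)
        assert np.allclose(ta.rmsd_series(traj), 0.0, atol=1e-9)

    def test_translated_frames_zero_rmsd(self, small_ref):
        frames = np.stack([small_ref.coords() + np.array([i, 0.0, 0.0])
                           for i in range(5)])
        traj = ta.Trajectory.from_frames(small_ref, frames)
        assert np.allclose(ta.rmsd_series(traj), 0.0, atol=1e-9)

    def test_two_state_series_matches_planted_separation(self, small_ref):
        other = synth.build_ideal_peptide("AKEAVADLAKEA", phi=-139, psi=135)
        mask_name = "backbone"
        traj, labels = synth.two_state_trajectory(small_ref, other, 0.5, 200,
                                                  within_sigma_nm=0.003, seed=3)
        mask = traj.selection(mask_name)
        _, _, sep = ta.kabsch_fit(small_ref.coords()[mask], other.coords()[mask])
        series = ta.rmsd_series(traj, reference=small_ref.coords())
        in_b = series[labels == 1]
        assert np.median(in_b) == pytest.approx(sep / 10.0, rel=0.03)

    def test_empty_selection_raises(self, noisy_traj):
        with pytest.raises(ValueError):
            ta.rmsd_series(noisy_traj, selection=np.zeros(noisy_traj.n_atoms, bool))


class TestRMSF:
    def test_identical_frames_zero(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.0, 4, seed=0)
        prof = ta.rmsf(traj)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_planted_sigma_sqrt3_expectation(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.1, 10000, seed=11,
                                               prealigned=True)
        prof = ta.rmsf(traj, selection="ca", fit=False)
        expected = np.sqrt(3.0) * 0.1
        assert np.nanmean(prof.rmsf) == pytest.approx(expected, rel=0.05)
        assert np.all(np.abs(prof.rmsf - expected) / expected < 0.05)

    def test_floppy_segment_tops_ranking_with_fitting(self, small_ref):
        sigma = [0.03] * 12
        for i in (5, 6, 7):
            sigma[i] = 0.3
        traj, _ = synth.fluctuation_trajectory(small_ref, sigma, 400, seed=5)
        prof = ta.rmsf(traj, fit=True)
        top3 = set(np.argsort(prof.rmsf)[-3:])
        assert top3 == {5, 6, 7}

    def test_single_frame_rejected(self, small_ref):
        traj = ta.Trajectory.from_frames(small_ref, small_ref.coords()[None])
        with pytest.raises(ValueError):
            ta.rmsf(traj)


class TestRadiusOfGyration:
    def test_two_point_closed_form(self):
        rg = ta.radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                                   np.array([1.0, 1.0]))
        assert rg == pytest.approx(0.1, abs=1e-9)

    def test_uniform_ring_closed_form(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.column_stack([5.0 * np.cos(theta), 5.0 * np.sin(theta),
                                np.zeros_like(theta)])
        rg = ta.radius_of_gyration(ring, np.ones(100))
        assert rg == pytest.approx(0.5, abs=1e-9)

    def test_direct_sum_oracle(self, rng):
        x = rng.normal(size=(40, 3))
        m = rng.uniform(1, 20, size=40)
        com = (m[:, None] * x).sum(0) / m.sum()
        direct = np.sqrt(sum(mi * ((xi - com) ** 2).sum()
                             for mi, xi in zip(m, x)) / m.sum()) / 10.0
        assert ta.radius_of_gyration(x, m) == pytest.approx(direct, abs=1e-9)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            ta.radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


class TestRigidMotionInvariance:
    def test_all_metrics_invariant(self, noisy_traj, rng):
        base_rmsd = ta.rmsd_series(noisy_traj)
        base_rmsf = ta.rmsf(noisy_traj).rmsf
        base_rg = ta.rg_series(noisy_traj)
        moved = ta.Trajectory.from_frames(noisy_traj.topology,
                                          noisy_traj.frames.copy())
        R = random_rotation(rng)
        t = np.array([9.0, -2.0, 14.0])
        moved.frames = moved.frames @ R.T + t  # same motion on every frame
        assert np.allclose(ta.rmsd_series(moved), base_rmsd, atol=1e-6)
        assert np.allclose(ta.rmsf(moved).rmsf, base_rmsf, atol=1e-6)
        assert np.allclose(ta.rg_series(moved), base_rg, atol=1e-6)


class TestGromosClustering:
    def test_identical_frames_single_cluster(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.0, 8, seed=0)
        res = ta.gromos_cluster(traj, cutoff=0.5)
        assert res.n_clusters == 1
        assert set(res.assignments) == {0}

    def test_matches_exhaustive_reference_on_toys(self, small_ref):
        other = synth.build_ideal_peptide("AKEAVADLAKEA", phi=-139, psi=135)
        for seed in range(5):
            traj, _ = synth.two_state_trajectory(small_ref, other, 0.4, 25,
                                                 within_sigma_nm=0.05, seed=seed)
            res = ta.gromos_cluster(traj, cutoff=0.5)
            ref_assign, ref_centers = oracles.gromos_reference(
                res.rmsd_matrix.tolist(), 0.5)
            assert res.assignments.tolist() == ref_assign
            assert res.centers == ref_centers

    def test_two_planted_conformers_recovered(self, small_ref):
        other = synth.build_ideal_peptide("AKEAVADLAKEA", phi=-139, psi=135)
        traj, labels = synth.two_state_trajectory(small_ref, other, 0.5, 60,
                                                  within_sigma_nm=0.01, seed=9)
        res = ta.gromos_cluster(traj, cutoff=0.5)
        assert res.n_clusters == 2
        for c in range(2):
            assert len(set(labels[res.assignments == c])) == 1

    def test_cluster_count_non_increasing_in_cutoff(self, small_ref):
        other = synth.build_ideal_peptide("AKEAVADLAKEA", phi=-139, psi=135)
        traj, _ = synth.two_state_trajectory(small_ref, other, 0.5, 30,
                                             within_sigma_nm=0.08, seed=2)
        ns = [ta.gromos_cluster(traj, cutoff=c).n_clusters
              for c in (0.05, 0.1, 0.3, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_histogram_counts_all_pairs(self, noisy_traj):
        res = ta.gromos_cluster(noisy_traj, cutoff=0.5)
        n = len(res.frame_indices)
        assert res.rms_histogram[1].sum() == n * (n - 1) // 2

    def test_stride_semantics(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.01, 100, seed=0)
        assert ta.stride_from_time(traj, 5000.0) == 500  # 10 ps spacing
        res = ta.gromos_cluster(traj, cutoff=1.0, stride=10)
        assert len(res.frame_indices) == 10


class TestSASASeries:
    def test_rigid_trajectory_constant(self, small_ref):
        traj, _ = synth.fluctuation_trajectory(small_ref, 0.0, 3, seed=0)
        series = ta.sasa_series(traj, n_points=240)
        assert np.allclose(series, series[0], rtol=1e-9)

    def test_single_atom_analytic(self):
        from thermostruct.structure_io import Structure, Chain, Residue, Atom
        key = ("A", 1, "")
        res = Residue("A", 1, "", "GLY", [Atom(1, "CA", "C", "", np.zeros(3), 1.0, key)])
        s = Structure("one", [Chain("A", [res])])
        traj = ta.Trajectory.from_frames(s, np.zeros((2, 1, 3)))
        series = ta.sasa_series(traj, n_points=480)
        assert np.allclose(series, 4 * np.pi * 3.1 ** 2 / 100.0, rtol=1e-6)

    def test_separating_pair_non_decreasing(self):
        from thermostruct.structure_io import Structure, Chain, Residue, Atom
        key = ("A", 1, "")
        res = Residue("A", 1, "", "GLY",
                      [Atom(1, "CA", "C", "", np.zeros(3), 1.0, key),
                       Atom(2, "C", "C", "", np.array([2.0, 0, 0]), 1.0, key)])
        s = Structure("two", [Chain("A", [res])])
        frames = np.zeros((6, 2, 3))
        for f in range(6):
            frames[f, 1, 0] = 2.0 + f * 1.0
        traj = ta.Trajectory.from_frames(s, frames)
        series = ta.sasa_series(traj, n_points=480)
        assert all(a <= b + 1e-9 for a, b in zip(series, series[1:]))
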