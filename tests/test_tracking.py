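import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from awakepet import (GapError, GridSpec, RigidPose, TrackerConfig,
                      Trajectory, VoxelImage, default_marker_model,
                      detect_candidates, fit_rigid_pose, interpolate_pose,
                      match_markers, similarity_score, track_events,
                      validate_pose)
from awakepet.experiment import pose_errors_vs_truth


@pytest.fixture(scope="module")
def marker_model():
    return default_marker_model()


# ------------------------------------------------------------ detection

class TestDetectCandidates:
    GRID = GridSpec.centered((32, 32, 16), (1.5, 1.5, 1.5))

    def _gaussian_blob(self, center_mm, sigma_vox=1.0, amp=100.0):
        g = self.GRID
        xs = [g.voxel_centers(a) for a in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        r2 = sum((c - m) ** 2 for c, m in zip((X, Y, Z), center_mm))
        return amp * np.exp(-r2 / (2 * (sigma_vox * 1.5) ** 2))

    def test_subvoxel_blob_localised_within_fifth_of_voxel(self):
        truth = np.array([3.4, -5.2, 2.1])
        frame = VoxelImage(self.GRID, self._gaussian_blob(truth))
        cand = detect_candidates(frame)
        assert len(cand) == 1
        assert np.linalg.norm(cand[0] - truth) <= 0.2 * 1.5

    def test_all_zero_frame_gives_no_candidates(self):
        frame = VoxelImage(self.GRID, np.zeros(self.GRID.shape))
        assert len(detect_candidates(frame)) == 0

    def test_two_separated_blobs_give_two_candidates(self):
        a = self._gaussian_blob((0.0, 0.0, 0.0))
        b = self._gaussian_blob((7.5, 0.0, 0.0))       # 5 voxels apart
        frame = VoxelImage(self.GRID, a + b)
        assert len(detect_candidates(frame)) == 2

    def test_brightest_candidates_first_and_capped(self):
        vals = np.zeros(self.GRID.shape)
        rng = np.random.default_rng(0)
        spots = np.column_stack([rng.choice(np.arange(4, 28), size=14),
                                 rng.choice(np.arange(4, 28), size=14),
                                 rng.choice(np.arange(4, 12), size=14)])
        for k, s in enumerate(spots):
            vals[tuple(s)] = 50.0 + k
        frame = VoxelImage(self.GRID, vals)
        cfg = TrackerConfig(max_candidates=6, detect_threshold_frac=0.1)
        cand = detect_candidates(frame, cfg)
        assert len(cand) <= 6


# ------------------------------------------------------------ similarity

class TestSimilarityScore:
    def test_zero_under_rigid_transform(self, marker_model):
        rot = Rotation.from_euler("zyx", [33, -12, 7], degrees=True)
        pts = rot.apply(marker_model.points) + np.array([4.0, -8.0, 2.0])
        assert similarity_score(pts, marker_model) <= 1e-12

    def test_matches_independent_pairwise_formula(self, marker_model):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pts = rng.uniform(-15, 15, (4, 3))
            expected = 0.0
            for i, j in itertools.combinations(range(4), 2):
                dc = np.linalg.norm(pts[i] - pts[j])
                dm = np.linalg.norm(marker_model.points[i] - marker_model.points[j])
                expected += (dc - dm) ** 2
            assert similarity_score(pts, marker_model) == pytest.approx(expected,
                                                                        rel=1e-12)

    def test_isometry_invariance(self, marker_model):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-10, 10, (4, 3))
        base = similarity_score(pts, marker_model)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            moved = rot.apply(pts) + rng.uniform(-20, 20, 3)
            assert similarity_score(moved, marker_model) == pytest.approx(base,
                                                                          rel=1e-9)

    def test_duplicate_points_score_infinite(self, marker_model):
        pts = np.array(marker_model.points)
        pts[1] = pts[0]
        assert similarity_score(pts, marker_model) == np.inf


# ------------------------------------------------------------ matching

def _brute_force_match(candidates, model):
    """Independent exhaustive enumeration via the scalar scorer."""
    best, best_score = None, np.inf
    for sel in itertools.permutations(range(len(candidates)), 4):
        s = similarity_score(candidates[list(sel)], model)
        if s < best_score:
            best, best_score = sel, s
    return best, best_score


class TestMatchMarkers:
    def test_transformed_model_recovered_exactly(self, marker_model):
        rot = Rotation.from_euler("xyz", [5, 40, -20], degrees=True)
        pts = rot.apply(marker_model.points) + np.array([-3.0, 6.0, 1.0])
        result = match_markers(pts, marker_model)
        assert result is not None
        matched, _, score = result
        assert score <= 1e-12
        assert np.allclose(matched, pts)

    def test_true_subset_found_among_decoys(self, marker_model):
        """Transformed markers plus 6 uniform decoys in the head bounding
        box: the true subset must win in >= 95% of trials."""
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            rot = Rotation.random(rng=rng)
            shift = rng.uniform(-10, 10, 3)
            true_pts = rot.apply(marker_model.points) + shift
            decoys = rng.uniform(-16, 16, (6, 3)) + shift
            cand = np.vstack([true_pts, decoys])
            perm = rng.permutation(len(cand))
            result = match_markers(cand[perm], marker_model)
            if result is None:
                continue
            matched, _, _ = result
            if np.allclose(np.sort(matched, axis=0), np.sort(true_pts, axis=0),
                           atol=1e-9):
                hits += 1
        assert hits >= 95

    def test_agrees_with_brute_force_enumeration(self, marker_model):
        rng = np.random.default_rng(7)
        cfg = TrackerConfig(score_cap=np.inf)
        for _ in range(200):
            n = rng.integers(4, 9)
            cand = rng.uniform(-20, 20, (int(n), 3))
            result = match_markers(cand, marker_model, cfg)
            sel_bf, score_bf = _brute_force_match(cand, marker_model)
            assert result is not None
            _, sel, score = result
            assert score == pytest.approx(score_bf, rel=1e-12)
            assert tuple(sel) == sel_bf

    def test_too_few_candidates_is_no_match(self, marker_model):
        cand = marker_model.points[:3]
        assert match_markers(cand, marker_model) is None


# ------------------------------------------------------------ pose fit

class TestFitRigidPose:
    def test_identity_for_untransformed_model(self, marker_model):
        pose = fit_rigid_pose(marker_model.points, marker_model)
        assert np.allclose(pose.translation_mm, 0, atol=1e-12)
        assert pose.rotation.magnitude() <= 1e-12

    def test_recovers_30deg_rotation_and_shift(self, marker_model):
        rot = Rotation.from_euler("z", 30, degrees=True)
        shift = np.array([5.0, -3.0, 2.0])
        pose = fit_rigid_pose(rot.apply(marker_model.points) + shift, marker_model)
        assert np.rad2deg(pose.rotation.magnitude()) == pytest.approx(30.0, abs=1e-9)
        assert np.allclose(pose.translation_mm, shift, atol=1e-9)

    def test_noise_robustness_monte_carlo(self, marker_model):
        """With 0.1-mm isotropic marker noise the mean centroid
        translation error stays below 0.15 mm."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(1000):
            rot = Rotation.random(rng=rng)
            shift = rng.uniform(-5, 5, 3)
            noisy = rot.apply(marker_model.points) + shift \
                + 0.1 * rng.standard_normal((4, 3))
            pose = fit_rigid_pose(noisy, marker_model)
            c = marker_model.centroid
            errs.append(np.linalg.norm(pose.apply(c) - (rot.apply(c) + shift)))
        assert np.mean(errs) < 0.15

    def test_collinear_points_raise(self, marker_model):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            fit_rigid_pose(pts, marker_model)


# ------------------------------------------------------------ validation

class TestValidatePose:
    def test_noise_free_match_accepted_with_zero_residuals(self, marker_model):
        pose = fit_rigid_pose(marker_model.points, marker_model)
        ok, res = validate_pose(marker_model.points, marker_model, pose)
        assert ok
        assert np.allclose(res, 0, atol=1e-9)

    def test_marker_displaced_beyond_2mm_rejected(self, marker_model):
        pose = RigidPose.identity()
        matched = np.array(marker_model.points)
        matched[2] += np.array([0.0, 0.0, 3.0])       # 3-mm residual
        ok, res = validate_pose(matched, marker_model, pose)
        assert not ok
        assert res[2] == pytest.approx(3.0)

    def test_residuals_of_exactly_1p9mm_accepted(self, marker_model):
        """The 2-mm rule is inclusive: 1.9-mm residuals pass."""
        pose = RigidPose.identity()
        dirs = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]])
        matched = marker_model.points + 1.9 * dirs
        ok, res = validate_pose(matched, marker_model, pose)
        assert ok
        assert np.allclose(res, 1.9)

    def test_rejection_monotone_in_tolerance(self, marker_model):
        rng = np.random.default_rng(3)
        pose = RigidPose.identity()
        accepted_sets = []
        cases = [marker_model.points + rng.normal(0, 0.8, (4, 3))
                 for _ in range(50)]
        for tol in (2.0, 1.0, 0.5):
            cfg = TrackerConfig(residual_tol_mm=tol)
            accepted_sets.append({i for i, m in enumerate(cases)
                                  if validate_pose(m, marker_model, pose, cfg)[0]})
        assert accepted_sets[2] <= accepted_sets[1] <= accepted_sets[0]


# ------------------------------------------------------------ interpolation

class TestInterpolatePose:
    def _traj(self):
        poses = [
            RigidPose(0.0),
            RigidPose(32.0, translation_mm=[10.0, 0, 0]),
            RigidPose.from_rotation(64.0, Rotation.from_euler("z", 90, degrees=True),
                                    [10.0, 0, 0]),
        ]
        return Trajectory(poses, 32.0)

    def test_knot_time_returns_knot_pose(self):
        p = interpolate_pose(self._traj(), 32.0)
        assert np.allclose(p.translation_mm, [10, 0, 0])

    def test_midpoint_translation_is_halfway(self):
        p = interpolate_pose(self._traj(), 16.0)
        assert np.allclose(p.translation_mm, [5, 0, 0])

    def test_midpoint_rotation_is_slerp_half_angle(self):
        p = interpolate_pose(self._traj(), 48.0)
        assert np.rad2deg(p.rotation.magnitude()) == pytest.approx(45.0, abs=1e-9)

    def test_long_gap_raises(self):
        poses = [RigidPose(0.0), RigidPose(320.0, translation_mm=[5.0, 0, 0])]
        traj = Trajectory(poses, 32.0)
        with pytest.raises(GapError):
            interpolate_pose(traj, 160.0, max_gap_frames=5)


# ------------------------------------------------------------ pipeline

class TestTrackEvents:
    def test_static_scan_tracks_cleanly(self, static_scan, model, geom):
        """A motionless animal: nearly every frame accepted and the pose
        scatter across frames well below a voxel."""
        events, _ = static_scan
        sl = events.time_slice(0.0, 8000.0)
        traj, tracks = track_events(sl, model, geom, TrackerConfig())
        frac = sum(t.accepted for t in tracks) / len(tracks)
        assert frac >= 0.99
        trans = np.array([p.translation_mm for p in traj.accepted_poses()])
        assert np.all(trans.std(axis=0) < 0.5)

    def test_moving_scan_pose_errors_unbiased(self, moving_scan_2cm,
                                              tracked_2cm, model):
        """Accepted-pose centroid errors carry no appreciable systematic
        offset: the mean error stays below a tenth of a tracking voxel
        (a small bias toward the body mass is expected from background
        counts entering the centroid window)."""
        _, truth = moving_scan_2cm
        trajectory, _ = tracked_2cm
        from awakepet.pose import interpolate_trajectory
        poses = trajectory.accepted_poses()
        t = np.array([p.t_ms for p in poses])
        rot, trans, _ = interpolate_trajectory(truth, t)
        c = model.centroid
        err = np.array([p.apply(c) for p in poses]) - (rot.apply(c) + trans)
        assert np.all(np.abs(err.mean(axis=0)) < 0.15)

    def test_no_accepted_frames_raises_with_diagnostics(self, phantom, geom,
                                                        model):
        from awakepet import TrackingError, sample_trajectory, simulate_listmode
        activity, _, _ = phantom
        traj = sample_trajectory(500, 0.0, rotation_scale_deg_s=0.0, seed=9)
        events, _ = simulate_listmode(activity, None, traj, geom,   # no markers
                                      duration_ms=500, rate_cps=5e4, seed=9)
        with pytest.raises(TrackingError, match="no frames accepted"):
            track_events(events, model, geom, TrackerConfig())
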