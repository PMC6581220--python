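import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.transform import Rotation

from awakepet import (GridSpec, Lor, MuMap, ReconConfig, VoxelImage, acf,
                      body_outline_mumap, compute_sensitivity,
                      motion_corrected_recon, n_frames, osem_from_endpoints,
                      osem_listmode, raytrace, short_frame_images,
                      simulate_listmode)
from awakepet.pose import RigidPose, Trajectory
from awakepet.simulate import EventStream
from awakepet.volumes import SOFT_TISSUE_MU


def _static_traj(duration_ms, rot=None, trans=(0, 0, 0), accepted=None):
    rot = rot or Rotation.identity()
    poses = [RigidPose.from_rotation(t, rot, trans)
             for t in np.arange(0.0, duration_ms + 32, 32.0)]
    if accepted is not None:
        for i, p in enumerate(poses):
            p.accepted = accepted(i)
    return Trajectory(poses, 32.0)


# ------------------------------------------------------------ sensitivity

class TestSensitivity:
    def test_no_mumap_equals_zero_mumap(self, geom):
        grid = GridSpec.centered((24, 24, 8), (2.0, 2.0, 2.0))
        a = compute_sensitivity(geom, grid)
        b = compute_sensitivity(geom, grid, MuMap(grid, np.zeros(grid.shape)))
        assert np.array_equal(a.values, b.values)

    def test_rotational_symmetry_by_one_crystal_pitch(self, geom):
        grid = GridSpec.centered((40, 40, 4), (1.5, 1.5, 2.0))
        sens = compute_sensitivity(geom, grid)
        interp = RegularGridInterpolator(
            [grid.voxel_centers(a) for a in range(3)], sens.values)
        ang = 2 * np.pi / geom.n_crystals_per_ring
        rng = np.random.default_rng(2)
        n = 200
        r = rng.uniform(3, 24, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-1.5, 1.5, n)
        p = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        q = np.stack([r * np.cos(phi + ang), r * np.sin(phi + ang), z], axis=1)
        ratio = interp(p) / interp(q)
        assert np.all(np.abs(ratio - 1.0) < 0.01)

    def test_attenuation_strictly_reduces_central_sensitivity(self, geom):
        grid = GridSpec.centered((24, 24, 8), (2.0, 2.0, 2.0))
        x = grid.voxel_centers(0)[:, None, None]
        y = grid.voxel_centers(1)[None, :, None]
        mu = np.where(np.broadcast_to(x ** 2 + y ** 2 < 20 ** 2, grid.shape),
                      SOFT_TISSUE_MU, 0.0)
        free = compute_sensitivity(geom, grid)
        att = compute_sensitivity(geom, grid, MuMap(grid, mu))
        center = tuple(s // 2 for s in grid.shape)
        assert att.values[center] < free.values[center]

    def test_grid_outside_fov_raises(self, geom):
        far = GridSpec((8, 8, 8), (1.0, 1.0, 1.0), (500.0, 500.0, 0.0))
        with pytest.raises(ValueError):
            compute_sensitivity(geom, far)


# ------------------------------------------------------------ MLEM core

def _tiny_instance(seed=0, n_events=400):
    """A 2-D (single-slice) list-mode instance with random LORs."""
    grid = GridSpec.centered((12, 12, 1), (1.0, 1.0, 2.0))
    rng = np.random.default_rng(seed)
    phi1 = rng.uniform(0, 2 * np.pi, n_events)
    phi2 = phi1 + np.pi + rng.uniform(-1.0, 1.0, n_events)
    pa = np.stack([9 * np.cos(phi1), 9 * np.sin(phi1), np.zeros(n_events)], 1)
    pb = np.stack([9 * np.cos(phi2), 9 * np.sin(phi2), np.zeros(n_events)], 1)
    return grid, pa, pb


def _dense_matrix(grid, pa, pb):
    A = np.zeros((len(pa), int(np.prod(grid.shape))))
    for i in range(len(pa)):
        idx, lengths = raytrace(Lor(tuple(pa[i]), tuple(pb[i])), grid)
        flat = np.ravel_multi_index(idx.T, grid.shape) if len(idx) else []
        A[i, flat] = lengths
    return A


def test_listmode_mlem_matches_dense_matrix_mlem():
    """List-mode EM must agree with an explicit dense-matrix EM to 1e-6,
    and the data log-likelihood must not decrease over iterations."""
    grid, pa, pb = _tiny_instance()
    A = _dense_matrix(grid, pa, pb)
    keep = A.sum(axis=1) > 0
    A, pa, pb = A[keep], pa[keep], pb[keep]
    sens_vals = np.full(grid.shape, 1.0)
    sens = VoxelImage(grid, sens_vals)

    x = np.ones(A.shape[1])
    s = sens_vals.ravel()
    loglik = []
    n_iter = 6
    for _ in range(n_iter):
        f = A @ x
        x = x / s * (A.T @ (1.0 / f))
        loglik.append(np.sum(np.log(A @ x)) - np.sum(s * x))
    assert np.all(np.diff(loglik) > -1e-9)

    cfg = ReconConfig(n_subsets=1, n_iterations=n_iter, psf_sigma_mm=0.0)
    img = osem_from_endpoints(pa, pb, grid, cfg, sens, check_coverage=False)
    ref = x.reshape(grid.shape)
    scale = np.abs(ref).max()
    assert np.max(np.abs(img.values - ref)) / scale < 1e-6


def test_count_preservation_with_flat_sensitivity():
    """sum(image * sensitivity) equals the event count after every full
    EM iteration (no PSF, flat sensitivity)."""
    grid, pa, pb = _tiny_instance(seed=3, n_events=300)
    A = _dense_matrix(grid, pa, pb)
    keep = A.sum(axis=1) > 0
    pa, pb = pa[keep], pb[keep]
    sens = VoxelImage(grid, np.full(grid.shape, 2.5))
    for n_iter in (1, 3):
        cfg = ReconConfig(n_subsets=1, n_iterations=n_iter, psf_sigma_mm=0.0)
        img = osem_from_endpoints(pa, pb, grid, cfg, sens, check_coverage=False)
        assert np.sum(img.values * sens.values) == pytest.approx(len(pa), rel=1e-6)


def test_doubling_events_doubles_image_exactly():
    grid, pa, pb = _tiny_instance(seed=5, n_events=200)
    sens = VoxelImage(grid, np.full(grid.shape, 1.0))
    cfg = ReconConfig(n_subsets=1, n_iterations=4, psf_sigma_mm=0.0)
    img1 = osem_from_endpoints(pa, pb, grid, cfg, sens, check_coverage=False)
    img2 = osem_from_endpoints(np.repeat(pa, 2, axis=0), np.repeat(pb, 2, axis=0),
                               grid, cfg, sens, check_coverage=False)
    assert np.allclose(img2.values, 2.0 * img1.values, rtol=1e-12, atol=1e-12)


def test_point_source_reconstructs_at_true_position(geom):
    from awakepet.markers import MarkerModel
    pos_true = np.array([4.0, -6.0, 2.0])
    m = MarkerModel(points=np.array([pos_true, [30, 0, 0], [0, 30, 0], [0, 0, 14]]),
                    activities_kbq=np.array([370.0, 1e-9, 1e-9, 1e-9]),
                    activity_range_kbq=(0.0, 400.0))
    ev, _ = simulate_listmode(None, m, _static_traj(3000), geom,
                              duration_ms=3000, rate_cps=3e4, seed=13)
    grid = GridSpec.centered((32, 32, 16), (1.0, 1.0, 1.0))
    sens = compute_sensitivity(geom, grid)
    cfg = ReconConfig(n_subsets=4, n_iterations=4, psf_sigma_mm=0.0)
    img = osem_listmode(ev, geom, grid, cfg, sensitivity=sens)
    peak = np.unravel_index(np.argmax(img.values), img.values.shape)
    center = grid.center_of(np.array(peak, dtype=float))
    assert np.all(np.abs(center - pos_true) <= np.asarray(grid.voxel_size))


def test_uniform_cylinder_contrast(geom):
    grid = GridSpec.centered((40, 40, 16), (1.0, 1.0, 1.0))
    x = grid.voxel_centers(0)[:, None, None]
    y = grid.voxel_centers(1)[None, :, None]
    inside = np.broadcast_to(x ** 2 + y ** 2 <= 10 ** 2, grid.shape)
    act = VoxelImage(grid, np.where(inside, 100.0, 0.0), is_activity=True)
    ev, _ = simulate_listmode(act, None, _static_traj(4000), geom,
                              duration_ms=4000, rate_cps=3e5, seed=17)
    sens = compute_sensitivity(geom, grid)
    cfg = ReconConfig(n_subsets=8, n_iterations=4, psf_sigma_mm=0.0)
    img = osem_listmode(ev, geom, grid, cfg, sensitivity=sens)
    annulus = np.broadcast_to((x ** 2 + y ** 2 > 14 ** 2)
                              & (x ** 2 + y ** 2 < 18 ** 2), grid.shape)
    assert img.values[inside].mean() / max(img.values[annulus].mean(), 1e-12) >= 20


def test_events_outside_sensitivity_support_raise():
    grid, pa, pb = _tiny_instance(seed=7, n_events=50)
    sens_vals = np.full(grid.shape, 1.0)
    sens_vals[:, :6, :] = 0.0            # half the grid unsupported
    cfg = ReconConfig(n_subsets=1, n_iterations=1, psf_sigma_mm=0.0)
    with pytest.raises(ValueError, match="sensitivity"):
        osem_from_endpoints(pa, pb, grid, cfg, VoxelImage(grid, sens_vals))


# ------------------------------------------------------------ short frames

class TestShortFrames:
    def test_frame_count_for_20_min_scan(self):
        assert n_frames(1_200_000.0, 32.0) == 37_500

    def test_half_open_frame_assignment(self, geom):
        grid = GridSpec.centered((16, 16, 4), (4.0, 4.0, 8.0))
        t_us = np.array([0, 31_999, 32_000, 95_999], dtype=np.int64)
        # pair each crystal with the diametrically opposite one so every
        # LOR crosses the central grid
        ev = EventStream(t_us, np.array([0, 1, 2, 3]), np.array([96, 97, 98, 99]),
                         geom.name, duration_ms=96.0)
        frames = list(short_frame_images(ev, geom, grid))
        assert len(frames) == 3
        starts = [f[0] for f in frames]
        assert starts == [0.0, 32.0, 64.0]
        # events at t=0 and t=31.999 ms belong to frame 0; t=32.000 to frame 1
        sums = [f[1].values.sum() for f in frames]
        assert sums[0] > 0 and sums[1] > 0 and sums[2] > 0

    def test_per_frame_event_counts_partition_stream(self, geom, phantom):
        activity, _, _ = phantom
        ev, _ = simulate_listmode(activity, None, _static_traj(2000), geom,
                                  duration_ms=2000, rate_cps=5e4, seed=19)
        frame_us = 32_000
        counts = np.bincount(ev.t_us // frame_us,
                             minlength=n_frames(ev.duration_ms, 32.0))
        assert counts.sum() == len(ev)
        assert len(counts) == n_frames(2000.0, 32.0)


# ------------------------------------------------------------ attenuation

class TestAttenuation:
    def test_acf_is_one_without_attenuation(self):
        grid = GridSpec.centered((20, 20, 4), (1.0, 1.0, 2.0))
        mu = MuMap(grid, np.zeros(grid.shape))
        assert acf(mu, Lor((-30, 0, 0), (30, 0, 0))) == 1.0

    def test_acf_closed_form_for_1cm_path(self):
        """A 10-mm chord through mu = 0.097 /cm gives exp(0.097)."""
        grid = GridSpec((10, 10, 2), (1.0, 1.0, 2.0), (0.0, 0.0, -2.0))
        mu = MuMap(grid, np.full((10, 10, 2), SOFT_TISSUE_MU))
        val = acf(mu, Lor((-5.0, 4.5, 0.0), (15.0, 4.5, 0.0)))
        assert val == pytest.approx(np.exp(0.097), rel=1e-9)
        assert val == pytest.approx(1.1019, abs=1e-4)

    def test_acf_nondecreasing_in_chord_length(self):
        grid = GridSpec.centered((30, 30, 4), (1.0, 1.0, 2.0))
        x = grid.voxel_centers(0)[:, None, None]
        y = grid.voxel_centers(1)[None, :, None]
        mu = np.where(np.broadcast_to(x ** 2 + y ** 2 <= 12 ** 2, grid.shape),
                      SOFT_TISSUE_MU, 0.0)
        mumap = MuMap(grid, mu)
        offsets = [0.0, 4.0, 8.0, 11.0, 14.0]
        vals = [acf(mumap, Lor((-25.0, o, 0.0), (25.0, o, 0.0))) for o in offsets]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0)


class TestBodyOutline:
    def test_cylinder_mask_volume_and_mu_value(self, geom):
        grid = GridSpec.centered((40, 40, 16), (1.0, 1.0, 1.0))
        x = grid.voxel_centers(0)[:, None, None]
        y = grid.voxel_centers(1)[None, :, None]
        inside = np.broadcast_to(x ** 2 + y ** 2 <= 10 ** 2, grid.shape)
        act = VoxelImage(grid, np.where(inside, 100.0, 0.0), is_activity=True)
        ev, _ = simulate_listmode(act, None, _static_traj(4000), geom,
                                  duration_ms=4000, rate_cps=2e5, seed=23)
        sens = compute_sensitivity(geom, grid)
        cfg = ReconConfig(n_subsets=8, n_iterations=4, psf_sigma_mm=0.0)
        recon = osem_listmode(ev, geom, grid, cfg, sensitivity=sens)
        mumap = body_outline_mumap(recon, cfg)
        mask = mumap.mu > 0
        assert np.all(mumap.mu[mask] == SOFT_TISSUE_MU)
        assert mask.sum() == pytest.approx(inside.sum(), rel=0.10)

    def test_faint_second_blob_excluded(self):
        grid = GridSpec.centered((32, 32, 8), (1.0, 1.0, 1.0))
        vals = np.zeros(grid.shape)
        vals[4:12, 4:12, 2:6] = 100.0
        vals[22:26, 22:26, 2:6] = 1.0       # 100x fainter, disconnected
        mumap = body_outline_mumap(VoxelImage(grid, vals))
        assert np.all(mumap.mu[22:26, 22:26, 2:6] == 0.0)
        assert np.all(mumap.mu[5:11, 5:11, 3:5] == SOFT_TISSUE_MU)

    def test_degenerate_threshold_raises(self):
        rng = np.random.default_rng(0)
        grid = GridSpec.centered((24, 24, 8), (1.0, 1.0, 1.0))
        vals = rng.uniform(0.9, 1.1, grid.shape)
        cfg = ReconConfig(outline_threshold_frac=0.99)
        with pytest.raises(ValueError):
            body_outline_mumap(VoxelImage(grid, vals), cfg)

    def test_all_zero_image_raises(self):
        grid = GridSpec.centered((8, 8, 8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            body_outline_mumap(VoxelImage(grid, np.zeros(grid.shape)))


# ------------------------------------------------------------ motion corr.

class TestMotionCorrection:
    def test_identity_trajectory_equals_plain_osem(self, geom, phantom,
                                                   head_grid, sens_head):
        activity, _, _ = phantom
        ev, traj = simulate_listmode(activity, None, _static_traj(1500), geom,
                                     duration_ms=1500, rate_cps=1e5, seed=29)
        cfg = ReconConfig(n_subsets=4, n_iterations=2, psf_sigma_mm=0.0)
        plain = osem_listmode(ev, geom, head_grid, cfg, sensitivity=sens_head)
        moco = motion_corrected_recon(ev, traj, geom, head_grid, cfg,
                                      sensitivity=sens_head)
        assert np.array_equal(plain.values, moco.values)

    def test_global_rigid_offset_leaves_correction_unchanged(self, geom, phantom,
                                                             head_grid, sens_head):
        """Motion-correction identity: left-composing every pose of a
        moving trajectory with one fixed rigid transform (the animal does
        the same dance elsewhere in the bore) leaves the corrected
        head-frame reconstruction unchanged up to noise and interpolation
        tolerance.  Regional means follow the quantification convention
        (common 1-mm post-filter) since the arms are independent count
        realizations."""
        from awakepet import default_marker_model, regional_means, \
            sample_trajectory, smooth_image
        activity, _, atlas = phantom
        model = default_marker_model()
        base = sample_trajectory(6000, 2.0, rest_fraction=0.0, seed=41)
        Q = Rotation.from_euler("z", 18, degrees=True)
        tq = np.array([6.0, -4.0, 1.5])
        shifted = Trajectory(
            [RigidPose.from_rotation(p.t_ms, Q * p.rotation,
                                     Q.apply(p.translation_mm) + tq)
             for p in base.poses], base.frame_duration_ms)
        cfg = ReconConfig(n_subsets=8, n_iterations=4, psf_sigma_mm=0.0)
        imgs = []
        for tr, seed in ((base, 43), (shifted, 43)):
            ev, _ = simulate_listmode(activity, model, tr, geom,
                                      duration_ms=6000, rate_cps=2.5e5, seed=seed)
            imgs.append(motion_corrected_recon(ev, tr, geom, head_grid, cfg,
                                               sensitivity=sens_head))
        rm_a = regional_means(smooth_image(imgs[0], 1.0), atlas)
        rm_b = regional_means(smooth_image(imgs[1], 1.0), atlas)
        for region in rm_a:
            assert rm_b[region] == pytest.approx(rm_a[region], rel=0.05)

    def test_rejected_frame_events_are_excluded(self, geom):
        """With frames 10-20 rejected (an 11-frame gap, beyond the 5-frame
        interpolation limit), exactly the events outside [320, 672) ms
        drive the reconstruction."""
        from awakepet.pose import interpolate_trajectory
        tr = _static_traj(2048, accepted=lambda i: not (10 <= i <= 20))
        t_query = np.arange(0.0, 2048.0, 1.0) + 0.5
        _, _, valid = interpolate_trajectory(tr, t_query, max_gap_ms=5 * 32.0)
        excluded = ~valid
        lo, hi = 10 * 32.0, 21 * 32.0
        assert np.array_equal(excluded, (t_query >= lo) & (t_query < hi))

    def test_no_accepted_poses_raises(self, geom, phantom, head_grid, sens_head):
        activity, _, _ = phantom
        ev, _ = simulate_listmode(activity, None, _static_traj(500), geom,
                                  duration_ms=500, rate_cps=5e4, seed=37)
        tr = _static_traj(500, accepted=lambda i: False)
        with pytest.raises(ValueError):
            motion_corrected_recon(ev, tr, geom, head_grid,
                                   ReconConfig(n_subsets=1, n_iterations=1),
                                   sensitivity=sens_head)
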