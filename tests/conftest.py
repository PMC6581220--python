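"""Shared fixtures: desk-scale geometry, phantom, and the simulated scans
reused across tracking/reconstruction/acceptance tests (session-scoped
because simulation and reconstruction dominate the suite's runtime).

Study conditions: the test-retest regime moves at 2 cm/s with rest bouts
(~35% resting), the memantine regime at 4 cm/s with almost no rest;
marker activities sit in the 296-370 kBq range against an FDG-realistic
phantom, giving a ~24% marker share of counts.  Quantification scans are
25 s at a detected ~6e4 cps; tracking-accuracy scans use 12-s slices
(~7e5 events).
"""
from __future__ import annotations

import numpy as np
import pytest

from awakepet import (ReconConfig, TrackerConfig, compute_sensitivity,
                      default_marker_model, desk_head_grid, desk_scanner,
                      make_head_phantom, motion_corrected_recon,
                      osem_listmode, sample_trajectory, simulate_listmode,
                      track_events, world_sensitivity_grid)

QUANT_SCAN_MS = 25_000.0
TRACK_SCAN_MS = 12_000.0
RATE_CPS = 2.5e5


@pytest.fixture(scope="session")
def geom():
    return desk_scanner()


@pytest.fixture(scope="session")
def head_grid():
    return desk_head_grid()


@pytest.fixture(scope="session")
def phantom(head_grid):
    """(activity, mumap, atlas) head phantom on the desk grid."""
    return make_head_phantom(head_grid, None)


@pytest.fixture(scope="session")
def model():
    return default_marker_model()


@pytest.fixture(scope="session")
def sens_head(geom, head_grid):
    return compute_sensitivity(geom, head_grid)


@pytest.fixture(scope="session")
def sens_world(geom, head_grid):
    return compute_sensitivity(
        geom, world_sensitivity_grid(geom, float(min(head_grid.voxel_size))))


@pytest.fixture(scope="session")
def recon_cfg():
    """Full-depth reconstruction; resolution modelling off because the
    simulator produces unblurred LORs."""
    return ReconConfig(n_subsets=16, n_iterations=8, psf_sigma_mm=0.0)


@pytest.fixture(scope="session")
def moving_scan_2cm(phantom, model, geom):
    """Test-retest-regime scan: 2 cm/s with rest bouts, 25 s."""
    activity, _, _ = phantom
    traj = sample_trajectory(QUANT_SCAN_MS, 2.0, rest_fraction=0.35, seed=101)
    events, _ = simulate_listmode(activity, model, traj, geom,
                                  duration_ms=QUANT_SCAN_MS, rate_cps=RATE_CPS,
                                  seed=101)
    return events, traj


@pytest.fixture(scope="session")
def moving_scan_4cm(phantom, model, geom):
    """Memantine-regime scan: 4 cm/s, almost no rest, 12 s."""
    activity, _, _ = phantom
    traj = sample_trajectory(TRACK_SCAN_MS, 4.0, rest_fraction=0.05, seed=102)
    events, _ = simulate_listmode(activity, model, traj, geom,
                                  duration_ms=TRACK_SCAN_MS, rate_cps=RATE_CPS,
                                  seed=102)
    return events, traj


@pytest.fixture(scope="session")
def static_scan(phantom, model, geom):
    """Matched-count static (motion-free) scan, 25 s."""
    activity, _, _ = phantom
    traj = sample_trajectory(QUANT_SCAN_MS, 0.0, rotation_scale_deg_s=0.0,
                             seed=103)
    events, _ = simulate_listmode(activity, model, traj, geom,
                                  duration_ms=QUANT_SCAN_MS, rate_cps=RATE_CPS,
                                  seed=103)
    return events, traj


@pytest.fixture(scope="session")
def tracked_2cm(moving_scan_2cm, model, geom):
    """Tracking of the full 25-s quantification scan."""
    events, _ = moving_scan_2cm
    trajectory, tracks = track_events(events, model, geom, TrackerConfig())
    return trajectory, tracks


@pytest.fixture(scope="session")
def tracked_2cm_slice(moving_scan_2cm, model, geom):
    """Tracking of a 12-s slice (tracking-accuracy problem size)."""
    events, _ = moving_scan_2cm
    sl = events.time_slice(0.0, TRACK_SCAN_MS)
    trajectory, tracks = track_events(sl, model, geom, TrackerConfig())
    return trajectory, tracks, len(sl)


@pytest.fixture(scope="session")
def tracked_4cm(moving_scan_4cm, model, geom):
    events, _ = moving_scan_4cm
    trajectory, tracks = track_events(events, model, geom, TrackerConfig())
    return trajectory, tracks


@pytest.fixture(scope="session")
def img_static(static_scan, geom, head_grid, recon_cfg, sens_head):
    events, _ = static_scan
    return osem_listmode(events, geom, head_grid, recon_cfg,
                         sensitivity=sens_head)


@pytest.fixture(scope="session")
def img_moco_truth(moving_scan_2cm, geom, head_grid, recon_cfg, sens_head,
                   sens_world):
    events, traj = moving_scan_2cm
    return motion_corrected_recon(events, traj, geom, head_grid, recon_cfg,
                                  sensitivity=sens_head,
                                  world_sensitivity=sens_world)


@pytest.fixture(scope="session")
def img_moco_tracked(moving_scan_2cm, tracked_2cm, geom, head_grid,
                     recon_cfg, sens_head, sens_world):
    events, _ = moving_scan_2cm
    trajectory, _ = tracked_2cm
    return motion_corrected_recon(events, trajectory, geom, head_grid,
                                  recon_cfg, sensitivity=sens_head,
                                  world_sensitivity=sens_world)
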