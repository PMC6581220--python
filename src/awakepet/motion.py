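"""Synthetic head-motion trajectories.

A freely moving mouse on a 10 x 9 cm platform is emulated by a smooth
Ornstein-Uhlenbeck-style random walk: head velocity follows an AR(1)
process in x and y (plus small z bobbing), positions are folded back at
the platform walls and softly confined to the scanner's transaxial field
of view, and head orientation performs a yaw-dominant angular random
walk.  Rest/move bouts reproduce the episodic locomotion of the
test-retest condition; the memantine-challenge condition is emulated
simply by a higher mean speed and near-zero rest fraction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pose import RigidPose, Trajectory

__all__ = ["PlatformBounds", "sample_trajectory"]


@dataclass(frozen=True)
class PlatformBounds:
    """Horizontal platform the animal can move on (mm)."""

    x_extent: float = 100.0
    y_extent: float = 90.0

    def __post_init__(self) -> None:
        if self.x_extent <= 0 or self.y_extent <= 0:
            raise ValueError("platform extents must be positive")

    @property
    def half(self) -> np.ndarray:
        return np.array([self.x_extent / 2.0, self.y_extent / 2.0])


def _fold(x: np.ndarray, lim: float) -> np.ndarray:
    """Reflect coordinates into [-lim, lim] (billiard fold)."""
    period = 4.0 * lim
    y = np.mod(x + lim, period)
    y = np.where(y > 2.0 * lim, period - y, y) - lim
    return y


def _rest_mask(n: int, dt_s: float, rest_fraction: float, rng,
               mean_move_s: float = 3.0) -> np.ndarray:
    """Alternating move/rest bouts with exponential durations; True = resting."""
    if rest_fraction <= 0:
        return np.zeros(n, dtype=bool)
    mean_rest_s = mean_move_s * rest_fraction / max(1e-9, 1.0 - rest_fraction)
    mask = np.zeros(n, dtype=bool)
    i, resting = 0, bool(rng.random() < rest_fraction)
    while i < n:
        mean = mean_rest_s if resting else mean_move_s
        length = max(1, int(round(rng.exponential(mean) / dt_s)))
        mask[i:i + length] = resting
        i += length
        resting = not resting
    return mask


def sample_trajectory(duration_ms: float,
                      mean_speed_cm_s: float,
                      bounds: PlatformBounds | None = None,
                      rotation_scale_deg_s: float = 45.0,
                      rest_fraction: float = 0.0,
                      seed: int | None = None,
                      frame_ms: float = 32.0,
                      max_radius_mm: float = 35.0,
                      z_bob_mm: float = 1.0,
                      velocity_tau_s: float = 0.5) -> Trajectory:
    """Sample a head trajectory at ``frame_ms`` resolution.

    The returned trajectory has one pose per frame boundary (0, 32, 64,
    ... ms, inclusive of the final boundary, so it covers the whole scan).
    The empirical mean centroid speed of the output equals
    ``mean_speed_cm_s`` up to small wall-folding corrections, because the
    sampled velocity process is rescaled to that mean before integration.

    ``max_radius_mm`` softly confines the head centre to the scanner's
    useful transaxial field of view: the animal's body occupies most of
    the platform, so the head does not reach the platform corners.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if mean_speed_cm_s < 0:
        raise ValueError("mean speed must be nonnegative")
    bounds = bounds or PlatformBounds()
    rng = np.random.default_rng(seed)
    dt_s = frame_ms / 1000.0
    n = int(np.ceil(round(duration_ms / frame_ms, 9))) + 1
    times = np.arange(n) * frame_ms

    # --- translation: AR(1) velocity, rescaled to the target mean speed ---
    rho = np.exp(-dt_s / velocity_tau_s)
    innov = rng.standard_normal((n, 2))
    v = np.empty((n, 2))
    v[0] = innov[0]
    for k in range(1, n):
        v[k] = rho * v[k - 1] + np.sqrt(1.0 - rho * rho) * innov[k]
    v[_rest_mask(n, dt_s, rest_fraction, rng)] = 0.0
    speeds = np.linalg.norm(v, axis=1)
    mean_speed_mm_s = 10.0 * mean_speed_cm_s
    if mean_speed_mm_s > 0 and speeds.mean() > 0:
        v *= mean_speed_mm_s / speeds.mean()
    else:
        v[:] = 0.0

    pos_xy = np.cumsum(np.vstack([np.zeros(2), v[:-1] * dt_s]), axis=0)
    half = bounds.half
    lim = np.minimum(half, max_radius_mm) if max_radius_mm else half
    pos_xy = np.stack([_fold(pos_xy[:, 0], lim[0]),
                       _fold(pos_xy[:, 1], lim[1])], axis=1)
    if max_radius_mm:
        # keep the head centre inside the scanner's useful transaxial FOV:
        # reflect radially (one pass suffices since r < 2 * max_radius)
        r = np.linalg.norm(pos_xy, axis=1)
        over = r > max_radius_mm
        if np.any(over):
            pos_xy[over] *= ((2 * max_radius_mm - r[over]) / r[over])[:, None]

    # small vertical bobbing, OU with stationary SD z_bob_mm
    z = np.zeros(n)
    if z_bob_mm > 0 and mean_speed_mm_s > 0:
        rz = np.exp(-dt_s / 0.8)
        for k in range(1, n):
            z[k] = rz * z[k - 1] + z_bob_mm * np.sqrt(1 - rz * rz) * rng.standard_normal()
    pos = np.column_stack([pos_xy, z])

    # --- rotation: yaw-dominant angular random walk ---
    if rotation_scale_deg_s > 0:
        rates = np.empty((n, 3))
        rr = np.exp(-dt_s / 1.0)
        rates[0] = rng.standard_normal(3)
        for k in range(1, n):
            rates[k] = rr * rates[k - 1] + np.sqrt(1 - rr * rr) * rng.standard_normal(3)
        scale = np.deg2rad(rotation_scale_deg_s) * np.array([1.0, 0.25, 0.25])
        rates *= scale / np.sqrt(np.mean(rates ** 2, axis=0).clip(1e-12))
        # mild mean reversion keeps orientation near upright over long scans
        angles = np.zeros((n, 3))
        for k in range(1, n):
            angles[k] = angles[k - 1] * (1 - dt_s / 10.0) + rates[k] * dt_s
        rots = Rotation.from_euler("zyx", angles)
    else:
        rots = Rotation.identity(n)

    poses = [RigidPose.from_rotation(t, r, p)
             for t, r, p in zip(times, rots, pos)]
    return Trajectory(poses=poses, frame_duration_ms=frame_ms)
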