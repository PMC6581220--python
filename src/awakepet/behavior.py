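"""Behavioural readouts derived from the tracked head trajectory:
centroid track, average speed, total distance traveled, and horizontal
position (dwell-time) heat maps."""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .markers import MarkerModel
from .motion import PlatformBounds
from .pose import Trajectory

__all__ = ["HeadTrack", "Heatmap2D", "SpeedDistance", "head_track",
           "speed_and_distance", "position_heatmap"]


@dataclass
class HeadTrack:
    """Head-centroid positions, one per accepted frame."""

    times_ms: np.ndarray        # (n,)
    positions_mm: np.ndarray    # (n, 3)
    frame_duration_ms: float = 32.0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if len(self.times_ms) != len(self.positions_mm):
            raise ValueError("times and positions must align")
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("track times must be increasing")

    def __len__(self) -> int:
        return len(self.times_ms)


class SpeedDistance(NamedTuple):
    avg_speed_cm_s: float
    distance_m: float
    tracked_s: float
    n_gaps: int


@dataclass
class Heatmap2D:
    """Dwell time (seconds) per horizontal-position bin."""

    x_edges_mm: np.ndarray
    y_edges_mm: np.ndarray
    dwell_s: np.ndarray          # (nx, ny)
    total_tracked_s: float

    def plot(self, ax=None, log: bool = True):
        """Render the heat map (log time colour scale, platform rectangle)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import LogNorm

        if ax is None:
            _, ax = plt.subplots()
        norm = LogNorm(vmin=max(self.dwell_s[self.dwell_s > 0].min(), 1e-3),
                       vmax=self.dwell_s.max()) if log and self.dwell_s.max() > 0 else None
        m = ax.pcolormesh(self.x_edges_mm, self.y_edges_mm, self.dwell_s.T, norm=norm)
        ax.plot([self.x_edges_mm[0], self.x_edges_mm[-1], self.x_edges_mm[-1],
                 self.x_edges_mm[0], self.x_edges_mm[0]],
                [self.y_edges_mm[0], self.y_edges_mm[0], self.y_edges_mm[-1],
                 self.y_edges_mm[-1], self.y_edges_mm[0]], color="white", lw=1.5)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_aspect("equal")
        return ax, m


def head_track(trajectory: Trajectory, model: MarkerModel) -> HeadTrack:
    """Marker-centroid position through every accepted pose."""
    poses = trajectory.accepted_poses()
    if not poses:
        raise ValueError("trajectory has no accepted poses")
    c = model.centroid
    times = np.array([p.t_ms for p in poses])
    pos = np.array([p.apply(c) for p in poses])
    return HeadTrack(times, pos, trajectory.frame_duration_ms)


def speed_and_distance(track: HeadTrack,
                       gap_ms: float | None = None) -> SpeedDistance:
    """Total distance (sum of consecutive-sample displacements, metres) and
    average speed (cm/s) over the tracked duration.

    Intervals longer than ``gap_ms`` (default 5 frame durations) are
    tracking gaps: they are bridged by a straight line and counted in
    both distance and duration, but flagged in ``n_gaps``.
    """
    if len(track) < 2:
        return SpeedDistance(0.0, 0.0, 0.0, 0)
    if gap_ms is None:
        gap_ms = 5 * track.frame_duration_ms
    dt_ms = np.diff(track.times_ms)
    steps_mm = np.linalg.norm(np.diff(track.positions_mm, axis=0), axis=1)
    distance_m = float(steps_mm.sum() / 1000.0)
    tracked_s = float(dt_ms.sum() / 1000.0)
    n_gaps = int(np.count_nonzero(dt_ms > gap_ms))
    speed_cm_s = (distance_m * 100.0 / tracked_s) if tracked_s > 0 else 0.0
    return SpeedDistance(speed_cm_s, distance_m, tracked_s, n_gaps)


def position_heatmap(track: HeadTrack, bounds: PlatformBounds | None = None,
                     n_bins: int | tuple[int, int] = (50, 45)) -> Heatmap2D:
    """Horizontal dwell-time histogram: each tracked sample deposits one
    frame duration of dwell time into its (x, y) bin.  Bins cover the
    platform."""
    if len(track) == 0:
        raise ValueError("empty track")
    bounds = bounds or PlatformBounds()
    if isinstance(n_bins, int):
        n_bins = (n_bins, n_bins)
    hx, hy = bounds.half
    xe = np.linspace(-hx, hx, n_bins[0] + 1)
    ye = np.linspace(-hy, hy, n_bins[1] + 1)
    dt_s = track.frame_duration_ms / 1000.0
    H, _, _ = np.histogram2d(track.positions_mm[:, 0], track.positions_mm[:, 1],
                             bins=[xe, ye])
    return Heatmap2D(xe, ye, H * dt_s, total_tracked_s=len(track) * dt_s)
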