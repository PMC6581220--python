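"""Rigid-body poses and time-ordered trajectories.

A pose maps head-frame coordinates to the scanner frame:
``x_scanner = R @ x_head + t``.  Rotations are stored as unit quaternions
in scalar-first (w, x, y, z) order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = ["RigidPose", "Trajectory", "GapError", "interpolate_trajectory"]


class GapError(ValueError):
    """Raised when a pose is requested inside a tracking gap that is too
    long to interpolate across."""


def _as_unit_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {n} != 1")
    return q / n


@dataclass
class RigidPose:
    t_ms: float
    quat_wxyz: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accepted: bool = True

    def __post_init__(self) -> None:
        self.quat_wxyz = _as_unit_quat(self.quat_wxyz)
        self.translation_mm = np.asarray(self.translation_mm, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls, t_ms: float = 0.0, accepted: bool = True) -> "RigidPose":
        return cls(t_ms=t_ms, accepted=accepted)

    @classmethod
    def from_rotation(cls, t_ms: float, rotation: Rotation, translation_mm,
                      accepted: bool = True) -> "RigidPose":
        x, y, z, w = rotation.as_quat()
        return cls(t_ms, np.array([w, x, y, z]), translation_mm, accepted)

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quat_wxyz
        return Rotation.from_quat([x, y, z, w])

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points_head: np.ndarray) -> np.ndarray:
        """Map head-frame point(s) (..., 3) into the scanner frame."""
        return self.rotation.apply(np.atleast_2d(points_head)).reshape(np.shape(points_head)) \
            + self.translation_mm

    def apply_inverse(self, points_scanner: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_scanner) - self.translation_mm
        return self.rotation.inv().apply(p).reshape(np.shape(points_scanner))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (abs(abs(self.quat_wxyz[0]) - 1.0) < tol
                and np.all(np.abs(self.translation_mm) < tol))


@dataclass
class Trajectory:
    """Time-ordered rigid poses sampled at the tracking frame rate.

    ``knot_offset_ms`` records where within its frame each pose is
    stamped: 0 for frame starts (ground-truth trajectories), half a frame
    for frame centres (tracked trajectories).  Pose k's frame therefore
    spans ``[t_k - offset, t_k - offset + frame_duration)``.
    """

    poses: list[RigidPose]
    frame_duration_ms: float = 32.0
    knot_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        t = self.times_ms
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("pose times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def times_ms(self) -> np.ndarray:
        return np.array([p.t_ms for p in self.poses], dtype=float)

    @property
    def accepted_mask(self) -> np.ndarray:
        return np.array([p.accepted for p in self.poses], dtype=bool)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted_mask.sum())

    def accepted_poses(self) -> list[RigidPose]:
        return [p for p in self.poses if p.accepted]

    def arrays(self, accepted_only: bool = True):
        """(times, Rotation, translations) for the (accepted) poses."""
        poses = self.accepted_poses() if accepted_only else self.poses
        if not poses:
            raise ValueError("trajectory has no accepted poses")
        t = np.array([p.t_ms for p in poses])
        quats = np.array([[p.quat_wxyz[1], p.quat_wxyz[2], p.quat_wxyz[3], p.quat_wxyz[0]]
                          for p in poses])
        trans = np.array([p.translation_mm for p in poses])
        return t, Rotation.from_quat(quats), trans

    @property
    def span_ms(self) -> tuple[float, float]:
        t = self.times_ms
        return float(t[0]), float(t[-1])


def interpolate_trajectory(trajectory: Trajectory, t_ms: np.ndarray,
                           max_gap_ms: float | None = None):
    """Interpolate accepted poses at query times.

    Translation is linear, rotation is quaternion slerp between the
    bracketing accepted poses.  Queries outside the accepted span are
    clamped to the end poses.  Returns ``(rotations, translations, valid)``.

    With ``max_gap_ms`` set, queries inside a gap between accepted poses
    longer than that are invalid (``valid`` False; callers drop those
    events) — except queries falling within the frame of an accepted
    pose bordering the gap, which snap to that pose: events of an
    accepted frame still reconstruct with their frame's pose, while
    events of the rejected frames are excluded.
    """
    t_ms = np.atleast_1d(np.asarray(t_ms, dtype=float))
    tk, rot, trans = trajectory.arrays(accepted_only=True)
    valid = np.ones(t_ms.shape, dtype=bool)
    tq = t_ms.copy()
    if max_gap_ms is not None:
        off = trajectory.knot_offset_ms
        frame = trajectory.frame_duration_ms

        def in_frame_of(knot_times):
            lo = knot_times - off
            return (t_ms >= lo) & (t_ms < lo + frame)

        if len(tk) > 1:
            gaps = np.diff(tk)
            seg = np.clip(np.searchsorted(tk, t_ms, side="right") - 1, 0, len(tk) - 2)
            inside = (t_ms > tk[0]) & (t_ms < tk[-1])
            on_knot = np.isin(t_ms, tk)
            in_long_gap = inside & ~on_knot & (gaps[seg] > max_gap_ms)
            near_prev = in_frame_of(tk[seg])
            near_next = in_frame_of(tk[seg + 1])
            valid &= ~(in_long_gap & ~(near_prev | near_next))
            # snap long-gap queries inside an accepted frame onto its pose
            snap_prev = in_long_gap & near_prev
            snap_next = in_long_gap & ~near_prev & near_next
            tq = np.where(snap_prev, tk[seg], tq)
            tq = np.where(snap_next, tk[seg + 1], tq)
        # beyond the accepted span: valid only within the end frames
        valid &= (t_ms >= tk[0] - off) & (t_ms < tk[-1] - off + frame)
    tq = np.clip(tq, tk[0], tk[-1])
    if len(tk) == 1:
        n = len(t_ms)
        return (Rotation.from_quat(np.tile(rot.as_quat(), (n, 1))),
                np.tile(trans[0], (n, 1)), valid)
    rq = Slerp(tk, rot)(tq)
    pq = np.stack([np.interp(tq, tk, trans[:, a]) for a in range(3)], axis=1)
    return rq, pq, valid
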