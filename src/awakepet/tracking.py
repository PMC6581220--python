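"""Point-source tracking (PST): head pose from fiducial markers.

Every 32-ms short frame is reconstructed, bright local maxima are
detected as point-source candidates, the four candidates matching the
rigid marker model are selected by minimising a purely geometric
similarity score (squared pairwise-distance discrepancy — blurring of
fast-moving sources makes shape-based descriptors unreliable, inter-point
distances are rigid invariants), the rigid pose is fitted by the Kabsch
least-squares alignment, and poses are validated against the model:
a frame with any marker residual above 2 mm is discarded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from .geometry import GridSpec, ScannerGeometry
from .markers import MarkerModel
from .pose import GapError, RigidPose, Trajectory, interpolate_trajectory
from .recon import ReconConfig, compute_sensitivity, short_frame_images
from .simulate import EventStream
from .volumes import VoxelImage

__all__ = ["TrackerConfig", "FrameTrack", "TrackingError", "detect_candidates",
           "similarity_score", "match_markers", "fit_rigid_pose",
           "validate_pose", "track_events", "interpolate_pose"]

_PAIRS = list(combinations(range(4), 2))


class TrackingError(RuntimeError):
    pass


@dataclass
class TrackerConfig:
    frame_ms: float = 32.0
    residual_tol_mm: float = 2.0
    max_candidates: int = 10
    detect_threshold_frac: float = 0.3
    min_markers_required: int = 4
    max_gap_frames: int = 5
    score_cap: float | None = None       # default 4 * residual_tol^2
    coarse_voxel_mm: float = 1.5
    quick_iterations: int = 3
    quick_subsets: int = 1

    def __post_init__(self) -> None:
        if self.residual_tol_mm <= 0:
            raise ValueError("residual_tol_mm must be positive")
        if self.max_candidates < 4:
            raise ValueError("max_candidates must be >= 4")

    @property
    def effective_score_cap(self) -> float:
        if self.score_cap is not None:
            return self.score_cap
        return 4.0 * self.residual_tol_mm ** 2


@dataclass
class FrameTrack:
    """Per-frame tracking record."""

    frame_start_ms: float
    candidates: np.ndarray                       # (n, 3) mm, brightest first
    matched: np.ndarray | None = None            # (4, 3) in model order
    score: float = np.inf
    pose: RigidPose | None = None
    residuals_mm: np.ndarray | None = None
    accepted: bool = False


def detect_candidates(frame: VoxelImage, cfg: TrackerConfig | None = None) -> np.ndarray:
    """Point-source candidates: local maxima of the lightly smoothed frame
    above a threshold fraction of the frame maximum, refined by an
    intensity-weighted centroid over the 3x3x3 neighbourhood.  Returns
    (n, 3) world coordinates (mm), brightest first, at most
    ``max_candidates``."""
    from scipy import ndimage

    cfg = cfg or TrackerConfig()
    # light pre-smoothing consolidates point sources whose counts split
    # across neighbouring voxels, so each source yields one stable peak;
    # the sub-voxel centroid is still computed on the raw counts
    raw = frame.values
    vals = ndimage.gaussian_filter(raw, sigma=0.6)
    vmax = vals.max()
    if vmax <= 0:
        return np.empty((0, 3))
    thresh = cfg.detect_threshold_frac * vmax
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_peak = (vals == ndimage.maximum_filter(vals, footprint=footprint,
                                              mode="constant")) & (vals >= thresh)
    peaks = np.argwhere(is_peak)
    if len(peaks) == 0:
        return np.empty((0, 3))
    intens = vals[tuple(peaks.T)]
    order = np.argsort(-intens, kind="stable")
    peaks = peaks[order][:cfg.max_candidates]

    # drop peaks adjacent to a brighter already-kept peak (plateau duplicates)
    kept: list[np.ndarray] = []
    for p in peaks:
        if any(np.max(np.abs(p - q)) <= 1 for q in kept):
            continue
        kept.append(p)
    peaks = np.array(kept)

    shape = np.asarray(frame.grid.shape)
    out = np.empty((len(peaks), 3))
    for i, p in enumerate(peaks):
        lo = np.maximum(p - 1, 0)
        hi = np.minimum(p + 2, shape)
        sub = raw[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
        w = sub.sum()
        centroid = np.array([float((g * sub).sum() / w) for g in grids])
        out[i] = frame.grid.center_of(centroid)
    return out


def similarity_score(candidate_subset: np.ndarray, model: MarkerModel) -> float:
    """Geometric similarity error: sum over the six unordered point pairs
    of (candidate distance - model distance)^2, mm^2.  Zero iff the
    ordered candidates reproduce the model's inter-point distances.
    Duplicate candidate points score +inf."""
    pts = np.asarray(candidate_subset, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("similarity_score needs exactly 4 ordered points")
    md = model.pair_distances
    score = 0.0
    for k, (i, j) in enumerate(_PAIRS):
        d = float(np.linalg.norm(pts[i] - pts[j]))
        if d < 1e-9:
            return np.inf
        score += (d - md[k]) ** 2
    return score


@lru_cache(maxsize=16)
def _arrangements(n: int) -> np.ndarray:
    """All ordered selections of 4 distinct indices out of n (n!/(n-4)!)."""
    return np.array(list(permutations(range(n), 4)), dtype=np.int64)


def match_markers(candidates: np.ndarray, model: MarkerModel,
                  cfg: TrackerConfig | None = None):
    """Exhaustively match candidates to the marker model.

    Evaluates the similarity score for every ordered 4-arrangement of the
    candidates and returns ``(points (4,3) in model order, indices, score)``
    for the global minimum, or ``None`` if fewer than
    ``min_markers_required`` candidates exist or the best score exceeds
    the score cap."""
    cfg = cfg or TrackerConfig()
    pts = np.asarray(candidates, dtype=float)
    if len(pts) < cfg.min_markers_required:
        return None
    arr = _arrangements(len(pts))
    diff = pts[:, None, :] - pts[None, :, :]
    D = np.sqrt((diff ** 2).sum(-1))
    md = model.pair_distances
    cand_d = np.stack([D[arr[:, i], arr[:, j]] for i, j in _PAIRS], axis=1)
    degenerate = np.any(cand_d < 1e-9, axis=1)
    scores = ((cand_d - md) ** 2).sum(axis=1)
    scores[degenerate] = np.inf
    best = int(np.argmin(scores))
    if not np.isfinite(scores[best]) or scores[best] > cfg.effective_score_cap:
        return None
    sel = arr[best]
    return pts[sel], sel, float(scores[best])


def fit_rigid_pose(matched: np.ndarray, model: MarkerModel,
                   t_ms: float = 0.0) -> RigidPose:
    """Least-squares rigid transform (Kabsch) mapping model points onto the
    matched points: minimises sum ||R m_i + t - p_i||^2 with det(R) = +1."""
    p = np.asarray(matched, dtype=float)
    if p.shape != (4, 3):
        raise ValueError("need 4 matched points in model order")
    m = model.points
    pc, mc = p.mean(0), m.mean(0)
    H = (m - mc).T @ (p - pc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8:
        raise ValueError("matched points are degenerate (collinear)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = pc - R @ mc
    from scipy.spatial.transform import Rotation
    return RigidPose.from_rotation(t_ms, Rotation.from_matrix(R), t)


def validate_pose(matched: np.ndarray, model: MarkerModel, pose: RigidPose,
                  cfg: TrackerConfig | None = None):
    """Per-marker residuals ||R m_i + t - p_i||; the pose is accepted iff
    the largest residual is <= residual_tol_mm (2 mm rule, inclusive)."""
    cfg = cfg or TrackerConfig()
    pred = pose.apply(model.points)
    residuals = np.linalg.norm(pred - np.asarray(matched, dtype=float), axis=1)
    return bool(np.max(residuals) <= cfg.residual_tol_mm), residuals


def default_tracking_grid(geom: ScannerGeometry, voxel_mm: float) -> GridSpec:
    """Coarse grid covering the whole transaxial FOV and axial extent."""
    n_xy = int(np.ceil(2 * geom.ring_radius / voxel_mm))
    n_z = max(4, int(np.ceil(geom.axial_fov / voxel_mm)))
    return GridSpec.centered((n_xy, n_xy, n_z), (voxel_mm,) * 3)


def track_events(events: EventStream, model: MarkerModel,
                 geom: ScannerGeometry, cfg: TrackerConfig | None = None,
                 grid_coarse: GridSpec | None = None):
    """Full tracking pipeline: short-frame reconstruction, candidate
    detection, model matching, pose fitting and validation.

    Returns ``(Trajectory, [FrameTrack])``.  Poses are stamped at frame
    centres.  Raises :class:`TrackingError` if no frame is accepted.
    """
    cfg = cfg or TrackerConfig()
    grid_coarse = grid_coarse or default_tracking_grid(geom, cfg.coarse_voxel_mm)
    quick = ReconConfig(n_subsets=cfg.quick_subsets, n_iterations=cfg.quick_iterations,
                        psf_sigma_mm=0.0)
    sens = compute_sensitivity(geom, grid_coarse)

    tracks: list[FrameTrack] = []
    poses: list[RigidPose] = []
    n_nomatch = 0
    for start, frame in short_frame_images(events, geom, grid_coarse,
                                           frame_ms=cfg.frame_ms, quick_cfg=quick,
                                           sensitivity=sens):
        t_center = start + cfg.frame_ms / 2.0
        cand = detect_candidates(frame, cfg)
        ft = FrameTrack(frame_start_ms=start, candidates=cand)
        match = match_markers(cand, model, cfg) if len(cand) else None
        if match is None:
            n_nomatch += 1
        else:
            matched, _, score = match
            ft.matched, ft.score = matched, score
            try:
                pose = fit_rigid_pose(matched, model, t_ms=t_center)
            except ValueError:
                pose = None
            if pose is not None:
                ok, res = validate_pose(matched, model, pose, cfg)
                pose.accepted = ok
                ft.pose, ft.residuals_mm, ft.accepted = pose, res, ok
                poses.append(pose)
        tracks.append(ft)

    accepted = sum(t.accepted for t in tracks)
    if accepted == 0:
        raise TrackingError(
            f"no frames accepted out of {len(tracks)} "
            f"({n_nomatch} without a model match)")
    traj = Trajectory(poses=poses, frame_duration_ms=cfg.frame_ms,
                      knot_offset_ms=cfg.frame_ms / 2.0)
    return traj, tracks


def interpolate_pose(trajectory: Trajectory, t_ms: float,
                     max_gap_frames: int = 5) -> RigidPose:
    """Pose at an arbitrary time: linear translation and quaternion slerp
    between the bracketing accepted poses; exact at knots.  Raises
    :class:`GapError` inside gaps longer than ``max_gap_frames`` frames."""
    max_gap_ms = max_gap_frames * trajectory.frame_duration_ms
    rot, trans, valid = interpolate_trajectory(trajectory, [t_ms], max_gap_ms)
    if not valid[0]:
        raise GapError(f"t={t_ms} ms falls in a tracking gap longer than "
                       f"{max_gap_frames} frames")
    from scipy.spatial.transform import Rotation
    q = rot.as_quat()
    q = q[0] if q.ndim == 2 else q
    return RigidPose.from_rotation(t_ms, Rotation.from_quat(q), trans[0])
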