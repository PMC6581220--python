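"""Synthetic list-mode coincidence simulation.

Events are generated by a simple analytic forward model: emission times
are a homogeneous Poisson process, emission sites are drawn from the
current total activity distribution (phantom voxels plus marker point
sources, both rigidly transformed by the head pose at the emission time),
the annihilation-photon pair direction is isotropic, and the event is
kept only if the line of response (LOR) intersects the detector cylinder
at two distinct crystals within the axial field of view.  If an
attenuation map is supplied, events are thinned with the survival
probability exp(-integral of mu along the LOR).  No scatter, randoms,
positron range or depth-of-interaction effects are modelled.

Timestamps are integer microseconds so that 32-ms framing is exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .markers import MarkerModel
from .pose import Trajectory, interpolate_trajectory
from .volumes import MuMap, VoxelImage

__all__ = ["EventStream", "simulate_listmode", "EmptyEmissionError"]

_FWHM_TO_SIGMA = 1.0 / 2.354820045


class EmptyEmissionError(ValueError):
    """Raised when there is nothing to emit (no phantom or marker activity)."""


@dataclass
class EventStream:
    """Timestamped detector-pair coincidences.

    ``t_us`` is nondecreasing; crystal indices refer to
    :attr:`ScannerGeometry.crystal_positions` of the named geometry.
    """

    t_us: np.ndarray                 # (N,) int64, microseconds
    crystal_a: np.ndarray            # (N,) int32
    crystal_b: np.ndarray            # (N,) int32
    geometry_name: str
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.crystal_a = np.asarray(self.crystal_a, dtype=np.int32)
        self.crystal_b = np.asarray(self.crystal_b, dtype=np.int32)
        if not (len(self.t_us) == len(self.crystal_a) == len(self.crystal_b)):
            raise ValueError("event columns must have equal length")
        if len(self.t_us) and np.any(np.diff(self.t_us) < 0):
            raise ValueError("timestamps must be nondecreasing")
        if np.any(self.crystal_a == self.crystal_b):
            raise ValueError("coincidence crystals must be distinct")

    def __len__(self) -> int:
        return len(self.t_us)

    @property
    def t_ms(self) -> np.ndarray:
        return self.t_us / 1000.0

    def select(self, mask_or_index) -> "EventStream":
        return EventStream(self.t_us[mask_or_index], self.crystal_a[mask_or_index],
                           self.crystal_b[mask_or_index], self.geometry_name,
                           self.duration_ms, dict(self.meta))

    def time_slice(self, start_ms: float, stop_ms: float) -> "EventStream":
        """Events with start_ms <= t < stop_ms (half-open).  Timestamps
        are kept as-is; the slice's ``duration_ms`` becomes ``stop_ms``
        so that frame indexing from t=0 still covers every event."""
        lo = np.searchsorted(self.t_us, int(round(start_ms * 1000)), side="left")
        hi = np.searchsorted(self.t_us, int(round(stop_ms * 1000)), side="left")
        out = self.select(slice(lo, hi))
        out.duration_ms = float(stop_ms)
        return out

    def endpoints(self, geom: ScannerGeometry) -> tuple[np.ndarray, np.ndarray]:
        pos = geom.crystal_positions
        return pos[self.crystal_a], pos[self.crystal_b]


def _sample_emission_sites(activity: VoxelImage | None, markers: MarkerModel | None,
                           n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` head-frame emission points.  Returns (points, is_marker)."""
    weights = []
    if activity is not None:
        vox_act = activity.values.ravel() * activity.grid.voxel_volume_cm3
        total_vox = float(vox_act.sum())
    else:
        vox_act, total_vox = None, 0.0
    total_mark = markers.total_activity_kbq if markers is not None else 0.0
    total = total_vox + total_mark
    if total <= 0:
        raise EmptyEmissionError("nothing to emit: zero phantom and marker activity")

    u = rng.random(n) * total
    from_marker = u >= total_vox
    pts = np.empty((n, 3))

    n_vox = int(np.count_nonzero(~from_marker))
    if n_vox:
        cdf = np.cumsum(vox_act)
        flat = np.searchsorted(cdf, u[~from_marker], side="right").clip(0, vox_act.size - 1)
        idx = np.stack(np.unravel_index(flat, activity.grid.shape), axis=1).astype(float)
        jitter = rng.random((n_vox, 3)) - 0.5
        pts[~from_marker] = (np.asarray(activity.grid.origin)
                             + (idx + 0.5 + jitter) * np.asarray(activity.grid.voxel_size))
    n_mark = n - n_vox
    if n_mark:
        mcdf = np.cumsum(markers.activities_kbq)
        mi = np.searchsorted(mcdf, (u[from_marker] - total_vox), side="right").clip(0, 3)
        sigma = markers.diameter_mm * _FWHM_TO_SIGMA
        pts[from_marker] = markers.points[mi] + sigma * rng.standard_normal((n_mark, 3))
    return pts, from_marker


def _detect_lors(points: np.ndarray, directions: np.ndarray, geom: ScannerGeometry):
    """Intersect emission rays with the detector cylinder.

    Returns (kept mask, crystal_a, crystal_b, endpoint_a, endpoint_b) for
    LORs that hit two distinct crystals within the axial FOV, with the
    emission point between the two hits.
    """
    R = geom.ring_radius
    p, d = points, directions
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1])
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - R * R
    disc = b * b - 4.0 * a * c
    ok = (a > 1e-12) & (disc > 0.0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    a_safe = np.where(ok, a, 1.0)
    t1 = (-b - sq) / (2 * a_safe)
    t2 = (-b + sq) / (2 * a_safe)
    ok &= (t1 < 0.0) & (t2 > 0.0)          # emission point inside the cylinder

    q1 = p + t1[:, None] * d
    q2 = p + t2[:, None] * d
    half_ax = geom.axial_fov / 2.0
    ok &= (np.abs(q1[:, 2]) < half_ax) & (np.abs(q2[:, 2]) < half_ax)

    def crystal_of(q):
        ring = np.floor((q[:, 2] + half_ax) / geom.crystal_axial_pitch).astype(np.int64)
        ring = np.clip(ring, 0, geom.n_rings - 1)
        phi = np.mod(np.arctan2(q[:, 1], q[:, 0]), 2 * np.pi)
        ti = np.floor(phi / (2 * np.pi) * geom.n_crystals_per_ring).astype(np.int64)
        ti = np.clip(ti, 0, geom.n_crystals_per_ring - 1)
        return ring * geom.n_crystals_per_ring + ti

    ca, cb = crystal_of(q1), crystal_of(q2)
    ok &= ca != cb
    return ok, ca, cb, q1, q2


def simulate_listmode(activity: VoxelImage | None,
                      markers: MarkerModel | None,
                      trajectory: Trajectory,
                      geom: ScannerGeometry,
                      mumap: MuMap | None = None,
                      duration_ms: float | None = None,
                      rate_cps: float = 5e4,
                      seed: int | None = None,
                      chunk: int = 500_000) -> tuple[EventStream, Trajectory]:
    """Simulate a list-mode acquisition.

    ``rate_cps`` is the emission (decay) rate driving the Poisson process;
    the detected coincidence rate is lower by the geometric acceptance
    fraction (and attenuation losses).  Poses are interpolated
    continuously between trajectory knots (translation lerp, rotation
    slerp), matching the interpolation used for motion correction.
    Deterministic for a fixed seed.  Returns the stream and the
    ground-truth trajectory.
    """
    if rate_cps <= 0:
        raise ValueError("rate_cps must be positive")
    t0, t1 = trajectory.span_ms
    if duration_ms is None:
        duration_ms = t1 - t0
    if duration_ms <= 0 or t1 - t0 < duration_ms - 1e-9:
        raise ValueError("trajectory must cover the requested duration")

    rng = np.random.default_rng(seed)
    n_emit = int(rng.poisson(rate_cps * duration_ms / 1000.0))
    static = all(p.is_identity() for p in trajectory.poses)

    out_t, out_a, out_b = [], [], []
    n_marker_kept = 0
    for start in range(0, n_emit, chunk):
        m = min(chunk, n_emit - start)
        times = rng.random(m) * duration_ms
        pts, is_marker = _sample_emission_sites(activity, markers, m, rng)

        if not static:
            rot, trans, _ = interpolate_trajectory(trajectory, times)
            world = rot.apply(pts) + trans
        else:
            world = pts

        cos_t = rng.uniform(-1.0, 1.0, m)
        phi = rng.uniform(0.0, 2 * np.pi, m)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        dirs = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)

        ok, ca, cb, q1, q2 = _detect_lors(world, dirs, geom)

        if mumap is not None and np.any(ok):
            from .recon import line_integrals
            idx = np.nonzero(ok)[0]
            if not static:
                rs, ts, _ = interpolate_trajectory(trajectory, times[idx])
                e1 = rs.apply(q1[idx] - ts, inverse=True)
                e2 = rs.apply(q2[idx] - ts, inverse=True)
            else:
                e1, e2 = q1[idx], q2[idx]
            integ = line_integrals(e1, e2, mumap.grid, mumap.mu)   # mu*mm
            survive = rng.random(len(idx)) < np.exp(-integ / 10.0)  # cm^-1 * mm
            keep = np.zeros(m, dtype=bool)
            keep[idx[survive]] = True
            ok = keep

        n_marker_kept += int(np.count_nonzero(ok & is_marker))
        out_t.append(np.round(times[ok] * 1000.0).astype(np.int64))
        out_a.append(ca[ok])
        out_b.append(cb[ok])

    t_us = np.concatenate(out_t) if out_t else np.empty(0, dtype=np.int64)
    ca = np.concatenate(out_a) if out_a else np.empty(0, dtype=np.int32)
    cb = np.concatenate(out_b) if out_b else np.empty(0, dtype=np.int32)
    order = np.argsort(t_us, kind="stable")
    stream = EventStream(
        t_us[order], ca[order], cb[order], geom.name, float(duration_ms),
        meta={"rate_cps": rate_cps, "seed": seed, "n_emitted": n_emit,
              "n_detected": int(len(order)), "n_marker_events": n_marker_kept,
              "attenuated": mumap is not None})
    return stream, trajectory
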