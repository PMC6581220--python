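"""List-mode OSEM reconstruction with resolution modelling, short-frame
reconstruction, event-by-event motion correction and outline-based
attenuation.

The reconstruction is ordered-subsets MLEM operating directly on
list-mode events (16 subsets, 8 iterations by default).  The system model
for an event is the Siddon intersection-length profile of its line of
response (LOR), optionally convolved with an isotropic image-space
Gaussian (resolution model).  Attenuation enters through the sensitivity
image: in the multiplicative list-mode update a per-event attenuation
factor cancels between numerator and denominator of the event ratio, so
only the (attenuated) sensitivity carries it.

Motion correction is event-by-event: each event's LOR endpoints are
mapped into the head reference frame by the inverse of the interpolated
pose at the event time; the sensitivity image is the exposure-weighted
average of the static sensitivity resampled through the accepted poses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _siddon
from .geometry import GridSpec, ScannerGeometry
from .pose import Trajectory, interpolate_trajectory
from .simulate import EventStream
from .volumes import SOFT_TISSUE_MU, MuMap, VoxelImage

__all__ = ["ReconConfig", "Lor", "raytrace", "line_integrals", "acf",
           "compute_sensitivity", "osem_listmode", "osem_from_endpoints",
           "short_frame_images", "n_frames", "motion_corrected_recon",
           "world_sensitivity_grid",
           "body_outline_mumap"]


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    ``psf_sigma_mm=None`` resolves to half the transaxial crystal pitch of
    the geometry in use (a simple stand-in for detector resolution).
    """

    n_subsets: int = 16
    n_iterations: int = 8
    psf_sigma_mm: float | None = None
    outline_threshold_frac: float = 0.10
    nonneg_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ValueError("n_subsets and n_iterations must be >= 1")
        if self.psf_sigma_mm is not None and self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be nonnegative")
        if not (0 < self.outline_threshold_frac < 1):
            raise ValueError("outline_threshold_frac must be in (0, 1)")

    def resolve_psf(self, geom: ScannerGeometry | None) -> float:
        if self.psf_sigma_mm is not None:
            return self.psf_sigma_mm
        if geom is None:
            return 0.0
        pitch = 2 * np.pi * geom.ring_radius / geom.n_crystals_per_ring
        return 0.5 * pitch


@dataclass(frozen=True)
class Lor:
    """A line of response between two endpoint coordinates (mm)."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.a, self.b):
            raise ValueError("LOR endpoints must be distinct")


def _grid_args(grid: GridSpec):
    return (np.asarray(grid.origin, dtype=np.float64),
            np.asarray(grid.voxel_size, dtype=np.float64),
            np.asarray(grid.shape, dtype=np.int64))


def raytrace(lor: Lor, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact Siddon traversal of a LOR through a grid.

    Returns ``(indices, lengths)`` where ``indices`` is an (n, 3) integer
    array of voxel indices and ``lengths`` the intersection lengths in mm.
    A LOR missing the grid returns empty arrays.
    """
    o, v, s = _grid_args(grid)
    nbuf = int(s.sum()) + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf)
    n = _siddon._trace_ray(np.asarray(lor.a, dtype=np.float64),
                           np.asarray(lor.b, dtype=np.float64),
                           o, v, s, idx_buf, len_buf)
    flat = idx_buf[:n]
    idx = np.stack(np.unravel_index(flat, tuple(grid.shape)), axis=1)
    return idx, len_buf[:n].copy()


def line_integrals(pa: np.ndarray, pb: np.ndarray, grid: GridSpec,
                   values: np.ndarray) -> np.ndarray:
    """Batched line integrals sum(value * length_mm) for rays pa->pb."""
    o, v, s = _grid_args(grid)
    pa = np.ascontiguousarray(pa, dtype=np.float64)
    pb = np.ascontiguousarray(pb, dtype=np.float64)
    out = np.empty(len(pa))
    _siddon.forward_project(pa, pb, o, v, s,
                            np.ascontiguousarray(values, dtype=np.float64).ravel(), out)
    return out


def acf(mumap: MuMap, lor: Lor) -> float:
    """Attenuation correction factor exp(integral of mu dl) >= 1."""
    a = np.asarray(lor.a, dtype=np.float64)[None]
    b = np.asarray(lor.b, dtype=np.float64)[None]
    integ = line_integrals(a, b, mumap.grid, mumap.mu)[0]   # cm^-1 * mm
    return float(np.exp(integ / 10.0))


def compute_sensitivity(geom: ScannerGeometry, grid: GridSpec,
                        mumap: MuMap | None = None,
                        max_pairs: int = 5_000_000) -> VoxelImage:
    """Per-voxel sum over detector pairs of geometric weight x attenuation
    survival.  Pair enumeration is strided down to ``max_pairs`` (and the
    result rescaled) for large geometries."""
    o, v, s = _grid_args(grid)
    crystals = np.ascontiguousarray(geom.crystal_positions)
    n_pairs = geom.n_crystals * (geom.n_crystals - 1) // 2
    stride = max(1, int(np.ceil(n_pairs / max_pairs)))
    out = np.zeros(int(np.prod(grid.shape)))
    if mumap is not None:
        if tuple(mumap.grid.shape) != tuple(grid.shape):
            raise ValueError("mumap grid must match reconstruction grid")
        mu_flat = np.ascontiguousarray(mumap.mu).ravel()
        use_mu = True
    else:
        mu_flat = np.zeros(1)
        use_mu = False
    _siddon.sensitivity_image(crystals, o, v, s, mu_flat, use_mu, stride, out)
    if out.max() <= 0:
        raise ValueError("grid lies entirely outside the scanner field of view")
    return VoxelImage(grid, out.reshape(grid.shape))


def _blur(values: np.ndarray, sigma_mm: float, grid: GridSpec) -> np.ndarray:
    if sigma_mm <= 0:
        return values
    sig = [sigma_mm / v for v in grid.voxel_size]
    return ndimage.gaussian_filter(values, sigma=sig, mode="constant")


def osem_from_endpoints(pa: np.ndarray, pb: np.ndarray, grid: GridSpec,
                        cfg: ReconConfig, sensitivity: VoxelImage,
                        psf_sigma_mm: float = 0.0,
                        check_coverage: bool = True) -> VoxelImage:
    """Core list-mode OSEM on precomputed LOR endpoints (mm).

    Subsets are formed by event index modulo ``n_subsets``; the update is
    the standard multiplicative list-mode EM step.  Deterministic.
    """
    if len(pa) == 0:
        raise ValueError("no events to reconstruct")
    o, v, s = _grid_args(grid)
    pa = np.ascontiguousarray(pa, dtype=np.float64)
    pb = np.ascontiguousarray(pb, dtype=np.float64)
    sens = sensitivity.values
    support = sens > 0

    if check_coverage:
        ones = np.ones(len(pa))
        bp = np.zeros(sens.size)
        _siddon.back_project(pa, pb, ones, o, v, s, bp)
        if np.any((bp.reshape(sens.shape) > 1e-9) & ~support):
            raise ValueError("events hit voxels with zero sensitivity; "
                             "geometry/grid mismatch")

    x = np.where(support, 1.0, 0.0)
    n_sub = cfg.n_subsets
    idx = np.arange(len(pa))
    subsets = [np.ascontiguousarray(np.nonzero(idx % n_sub == k)[0])
               for k in range(n_sub)]
    sens_sub = sens / n_sub
    for _ in range(cfg.n_iterations):
        for sel in subsets:
            if len(sel) == 0:
                continue
            xb = _blur(x, psf_sigma_mm, grid)
            fwd = np.empty(len(sel))
            _siddon.forward_project(pa[sel], pb[sel], o, v, s, xb.ravel(), fwd)
            ratio = np.zeros_like(fwd)
            np.divide(1.0, fwd, out=ratio, where=fwd > 1e-12)
            bp = np.zeros(x.size)
            _siddon.back_project(pa[sel], pb[sel], ratio, o, v, s, bp)
            bp = bp.reshape(x.shape)
            if psf_sigma_mm > 0:
                bp = _blur(bp, psf_sigma_mm, grid)
            x = np.where(support, x * bp / np.where(support, sens_sub, 1.0), 0.0)
            if cfg.nonneg_floor > 0:
                x = np.maximum(x, cfg.nonneg_floor)
    return VoxelImage(grid, x)


def osem_listmode(events: EventStream, geom: ScannerGeometry, grid: GridSpec,
                  cfg: ReconConfig | None = None,
                  sensitivity: VoxelImage | None = None,
                  mumap: MuMap | None = None) -> VoxelImage:
    """List-mode OSEM reconstruction of an event stream (static scan)."""
    cfg = cfg or ReconConfig()
    if len(events) == 0:
        raise ValueError("event stream is empty")
    if sensitivity is None:
        sensitivity = compute_sensitivity(geom, grid, mumap=mumap)
    pa, pb = events.endpoints(geom)
    return osem_from_endpoints(pa, pb, grid, cfg, sensitivity,
                               psf_sigma_mm=cfg.resolve_psf(geom))


def n_frames(duration_ms: float, frame_ms: float = 32.0) -> int:
    """Number of half-open [k*frame, (k+1)*frame) frames covering a scan."""
    return int(np.ceil(round(duration_ms / frame_ms, 9)))


def short_frame_images(events: EventStream, geom: ScannerGeometry,
                       grid_coarse: GridSpec, frame_ms: float = 32.0,
                       quick_cfg: ReconConfig | None = None,
                       sensitivity: VoxelImage | None = None):
    """Reconstruct consecutive short frames (default 32 ms); yields
    ``(frame_start_ms, VoxelImage)``.  Frames are half-open; an event at
    exactly t = k*frame_ms belongs to frame k.  Empty frames yield zero
    images.  Uses a fast configuration (2 plain MLEM iterations, no PSF)
    by default."""
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    quick_cfg = quick_cfg or ReconConfig(n_subsets=1, n_iterations=2, psf_sigma_mm=0.0)
    if sensitivity is None:
        sensitivity = compute_sensitivity(geom, grid_coarse)
    total = n_frames(events.duration_ms, frame_ms)
    frame_us = int(round(frame_ms * 1000))
    fidx = events.t_us // frame_us
    pos = geom.crystal_positions
    boundaries = np.searchsorted(fidx, np.arange(total + 1))
    for k in range(total):
        lo, hi = boundaries[k], boundaries[k + 1]
        start = k * frame_ms
        if hi == lo:
            yield start, VoxelImage(grid_coarse, np.zeros(grid_coarse.shape))
            continue
        pa = pos[events.crystal_a[lo:hi]]
        pb = pos[events.crystal_b[lo:hi]]
        img = osem_from_endpoints(pa, pb, grid_coarse, quick_cfg, sensitivity,
                                  psf_sigma_mm=quick_cfg.resolve_psf(None),
                                  check_coverage=False)
        yield start, img


def world_sensitivity_grid(geom: ScannerGeometry, voxel_mm: float = 2.0) -> GridSpec:
    """Grid covering the whole bore, for resampling sensitivity under
    motion (the sensitivity field is smooth, so 2-mm voxels suffice)."""
    n_xy = int(np.ceil(2 * geom.ring_radius / voxel_mm))
    n_z = int(np.ceil(geom.axial_fov / voxel_mm))
    return GridSpec.centered((n_xy, n_xy, n_z), (voxel_mm,) * 3)


def _pose_averaged_sensitivity(sens_world: VoxelImage, out_grid: GridSpec,
                               trajectory: Trajectory,
                               n_pose_samples: int = 64) -> VoxelImage:
    """Exposure-weighted average over accepted poses of the scanner-frame
    sensitivity sampled at each head voxel's world position — the
    head-frame sensitivity under motion.  ``sens_world`` should cover the
    whole region the head visits (see :func:`world_sensitivity_grid`)."""
    accepted = trajectory.accepted_poses()
    if not accepted:
        raise ValueError("trajectory has no accepted poses")
    if len(accepted) > n_pose_samples:
        sel = np.linspace(0, len(accepted) - 1, n_pose_samples).round().astype(int)
        accepted = [accepted[i] for i in np.unique(sel)]
    gw, gh = sens_world.grid, out_grid
    # per-voxel sensitivity scales with voxel volume; resample as a
    # density and convert to the output grid's voxel volume
    scale = gh.voxel_volume_mm3 / gw.voxel_volume_mm3
    Vh = np.diag(gh.voxel_size)
    Vw_inv = np.diag(1.0 / np.asarray(gw.voxel_size))
    org_h = np.asarray(gh.origin)
    org_w = np.asarray(gw.origin)
    half_h = 0.5 * np.asarray(gh.voxel_size)
    out = np.zeros(gh.shape)
    w = 1.0 / len(accepted)
    for p in accepted:
        R = p.matrix
        A = Vw_inv @ R @ Vh
        off = Vw_inv @ (R @ (org_h + half_h) + p.translation_mm - org_w) - 0.5
        out += w * ndimage.affine_transform(sens_world.values, A, offset=off,
                                            order=1, mode="nearest",
                                            output_shape=gh.shape)
    return VoxelImage(gh, out * scale)


def motion_corrected_recon(events: EventStream, trajectory: Trajectory,
                           geom: ScannerGeometry, grid: GridSpec,
                           cfg: ReconConfig | None = None,
                           mumap: MuMap | None = None,
                           sensitivity: VoxelImage | None = None,
                           world_sensitivity: VoxelImage | None = None,
                           n_pose_samples: int = 64,
                           max_gap_ms: float | None = None) -> VoxelImage:
    """Event-by-event motion-corrected OSEM in the head reference frame.

    Each event's LOR endpoints are transformed by the inverse of the pose
    interpolated at the event time; events falling in rejected-pose gaps
    longer than ``max_gap_ms`` (default 5 frames) are dropped.

    The sensitivity under motion is the exposure-weighted average over
    accepted poses of the scanner-frame (geometric) sensitivity sampled
    at each head voxel's world position; with an attenuation map the
    head-frame attenuation survival factor multiplies that average.
    ``sensitivity`` is the static head-grid sensitivity (computed with
    ``mumap`` if given); ``world_sensitivity`` the bore-covering
    geometric sensitivity — both are computed when not supplied.
    """
    cfg = cfg or ReconConfig()
    if trajectory.n_accepted == 0:
        raise ValueError("trajectory has no accepted poses")
    if max_gap_ms is None:
        max_gap_ms = 5 * trajectory.frame_duration_ms
    pa, pb = events.endpoints(geom)

    if sensitivity is None:
        sensitivity = compute_sensitivity(geom, grid, mumap=mumap)

    if all(p.is_identity() for p in trajectory.accepted_poses()) \
            and trajectory.n_accepted == len(trajectory):
        return osem_from_endpoints(pa, pb, grid, cfg, sensitivity,
                                   psf_sigma_mm=cfg.resolve_psf(geom))

    rot, trans, valid = interpolate_trajectory(trajectory, events.t_ms, max_gap_ms)
    pa_h = rot.apply(pa - trans, inverse=True)[valid]
    pb_h = rot.apply(pb - trans, inverse=True)[valid]
    if len(pa_h) == 0:
        raise ValueError("no events remain after gap exclusion")

    if world_sensitivity is None:
        world_sensitivity = compute_sensitivity(
            geom, world_sensitivity_grid(geom, float(min(grid.voxel_size))))
    sens_mc = _pose_averaged_sensitivity(world_sensitivity, grid, trajectory,
                                         n_pose_samples)
    if mumap is not None:
        # attenuation moves with the head: fold in the head-frame survival
        # factor of the static attenuated sensitivity
        geo = compute_sensitivity(geom, grid)
        factor = np.where(geo.values > 0, sensitivity.values
                          / np.where(geo.values > 0, geo.values, 1.0), 0.0)
        sens_mc = VoxelImage(grid, sens_mc.values * factor)
    return osem_from_endpoints(pa_h, pb_h, grid, cfg, sens_mc,
                               psf_sigma_mm=cfg.resolve_psf(geom))


def body_outline_mumap(uncorrected: VoxelImage,
                       cfg: ReconConfig | None = None) -> MuMap:
    """Attenuation map from the body activity outline.

    The body mask is the largest connected component above
    ``outline_threshold_frac`` x the robust (99.5th percentile) maximum of
    the uncorrected reconstruction, morphologically closed and
    hole-filled; mu = 0.097 cm^-1 inside, 0 outside.
    """
    cfg = cfg or ReconConfig()
    vals = uncorrected.values
    if not np.any(vals > 0):
        raise ValueError("uncorrected image has no positive values")
    robust_max = float(np.percentile(vals[vals > 0], 99.5))
    mask = vals >= cfg.outline_threshold_frac * robust_max
    labels, nlab = ndimage.label(mask)
    if nlab == 0 or mask.sum() < 10:
        raise ValueError("body outline mask is (near-)empty; "
                         "threshold too high for this image")
    largest = np.argmax(ndimage.sum_labels(np.ones_like(vals), labels,
                                           index=np.arange(1, nlab + 1))) + 1
    mask = labels == largest
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)))
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < 10:
        raise ValueError("body outline mask is (near-)empty after cleanup")
    return MuMap(uncorrected.grid, np.where(mask, SOFT_TISSUE_MU, 0.0))
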