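"""Numba kernels: Siddon-style exact ray traversal and list-mode projectors.

All kernels work on a regular grid described by (origin, voxel_size,
shape) in mm.  A ray is the segment between two endpoint coordinates;
traversal yields every voxel the segment crosses together with the exact
intersection length.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _trace_ray(p0, p1, origin, voxel, shape, idx_buf, len_buf):
    """Traverse the segment p0->p1.  Fills flat voxel indices and lengths
    (mm) into the buffers; returns the number of voxels crossed."""
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    L = np.sqrt(dx * dx + dy * dy + dz * dz)
    if L < _EPS:
        return 0
    d = (dx, dy, dz)
    tmin = 0.0
    tmax = 1.0
    for a in range(3):
        lo = origin[a]
        hi = origin[a] + shape[a] * voxel[a]
        if abs(d[a]) > _EPS:
            ta = (lo - p0[a]) / d[a]
            tb = (hi - p0[a]) / d[a]
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
        else:
            if p0[a] <= lo or p0[a] >= hi:
                return 0
    if tmax - tmin < _EPS:
        return 0

    # entry voxel (nudged inside to dodge exact-boundary ambiguity)
    t = tmin
    nudge = tmin + 1e-10 * (tmax - tmin)
    ix = int(np.floor((p0[0] + nudge * dx - origin[0]) / voxel[0]))
    iy = int(np.floor((p0[1] + nudge * dy - origin[1]) / voxel[1]))
    iz = int(np.floor((p0[2] + nudge * dz - origin[2]) / voxel[2]))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= shape[0]:
        ix = shape[0] - 1
    if iy >= shape[1]:
        iy = shape[1] - 1
    if iz >= shape[2]:
        iz = shape[2] - 1

    step = np.empty(3, dtype=np.int64)
    tnext = np.empty(3)
    tdelta = np.empty(3)
    i3 = np.empty(3, dtype=np.int64)
    i3[0], i3[1], i3[2] = ix, iy, iz
    for a in range(3):
        if d[a] > _EPS:
            step[a] = 1
            tnext[a] = (origin[a] + (i3[a] + 1) * voxel[a] - p0[a]) / d[a]
            tdelta[a] = voxel[a] / d[a]
        elif d[a] < -_EPS:
            step[a] = -1
            tnext[a] = (origin[a] + i3[a] * voxel[a] - p0[a]) / d[a]
            tdelta[a] = -voxel[a] / d[a]
        else:
            step[a] = 0
            tnext[a] = np.inf
            tdelta[a] = np.inf

    n = 0
    ny = shape[1]
    nz = shape[2]
    while t < tmax - _EPS:
        # next crossing
        a_min = 0
        tn = tnext[0]
        if tnext[1] < tn:
            tn = tnext[1]
            a_min = 1
        if tnext[2] < tn:
            tn = tnext[2]
            a_min = 2
        if tn > tmax:
            tn = tmax
        seg = (tn - t) * L
        if seg > 0.0:
            idx_buf[n] = (i3[0] * ny + i3[1]) * nz + i3[2]
            len_buf[n] = seg
            n += 1
        t = tn
        if t >= tmax - _EPS:
            break
        i3[a_min] += step[a_min]
        if i3[a_min] < 0 or i3[a_min] >= shape[a_min]:
            break
        tnext[a_min] += tdelta[a_min]
    return n


@njit(cache=True)
def forward_project(pa, pb, origin, voxel, shape, image_flat, out):
    """out[i] = sum_j length_ij * image[j] for each ray i."""
    nbuf = shape[0] + shape[1] + shape[2] + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf)
    for i in range(pa.shape[0]):
        n = _trace_ray(pa[i], pb[i], origin, voxel, shape, idx_buf, len_buf)
        s = 0.0
        for k in range(n):
            s += len_buf[k] * image_flat[idx_buf[k]]
        out[i] = s


@njit(cache=True)
def back_project(pa, pb, weights, origin, voxel, shape, out_flat):
    """out[j] += sum_i length_ij * weights[i]."""
    nbuf = shape[0] + shape[1] + shape[2] + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf)
    for i in range(pa.shape[0]):
        w = weights[i]
        if w == 0.0:
            continue
        n = _trace_ray(pa[i], pb[i], origin, voxel, shape, idx_buf, len_buf)
        for k in range(n):
            out_flat[idx_buf[k]] += len_buf[k] * w


@njit(cache=True)
def sensitivity_image(crystals, origin, voxel, shape, mu_flat, use_mu, stride, out_flat):
    """Sum of geometric weight (x attenuation survival) over crystal pairs.

    Enumerates pairs (i < j), keeping every ``stride``-th pair; the result
    is scaled by ``stride`` so its magnitude matches the full sum.
    """
    m = crystals.shape[0]
    nbuf = shape[0] + shape[1] + shape[2] + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf)
    c = 0
    for i in range(m):
        for j in range(i + 1, m):
            if c % stride != 0:
                c += 1
                continue
            c += 1
            n = _trace_ray(crystals[i], crystals[j], origin, voxel, shape,
                           idx_buf, len_buf)
            if n == 0:
                continue
            w = 1.0
            if use_mu:
                integ = 0.0
                for k in range(n):
                    integ += len_buf[k] * mu_flat[idx_buf[k]]
                w = np.exp(-integ / 10.0)   # mu in cm^-1, lengths in mm
            for k in range(n):
                out_flat[idx_buf[k]] += w * len_buf[k]
    if stride > 1:
        for k in range(out_flat.size):
            out_flat[k] *= stride
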