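"""Numba kernels: Siddon-style ray traversal and the sequential ART sweep.

The traversal enumerates, for the segment from the source point to a
detector-pixel centre, every voxel the segment crosses together with the
exact Euclidean intersection length — these lengths are the system-matrix
weights a_ij of the ray-sum model.  Ties at voxel corners are resolved by
advancing every axis whose crossing parameter equals the minimum, in the
fixed order x, y, z, which makes the enumeration deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# loop guard: a segment can cross at most nx+ny+nz+2 voxel boundaries
_EXTRA = 3


@njit(cache=True)
def _trace_one(sx, sy, sz, ex, ey, ez,
               ox, oy, oz, nx, ny, nz, vs,
               idx_out, w_out, base):
    """Trace one segment through the grid; write (linear voxel index,
    intersection length) pairs starting at ``base``; return the count."""
    dx = ex - sx
    dy = ey - sy
    dz = ez - sz
    seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg_len == 0.0:
        return 0

    tmin = 0.0
    tmax = 1.0
    # clip the unit-parameter segment against the grid bounding box
    for d, s, o, n in ((dx, sx, ox, nx), (dy, sy, oy, ny), (dz, sz, oz, nz)):
        lo = o
        hi = o + n * vs
        if d != 0.0:
            t0 = (lo - s) / d
            t1 = (hi - s) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
        elif s < lo or s > hi:
            return 0
    if tmax - tmin <= 1e-14:
        return 0

    # starting voxel from the entry point, nudged inside
    tm = tmin + 1e-12 * (tmax - tmin)
    ix = int(np.floor((sx + tm * dx - ox) / vs))
    iy = int(np.floor((sy + tm * dy - oy) / vs))
    iz = int(np.floor((sz + tm * dz - oz) / vs))
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nz:
        iz = nz - 1

    big = 1e300
    if dx > 0.0:
        stx, dtx = 1, vs / dx
        tx = (ox + (ix + 1) * vs - sx) / dx
    elif dx < 0.0:
        stx, dtx = -1, -vs / dx
        tx = (ox + ix * vs - sx) / dx
    else:
        stx, dtx, tx = 0, big, big
    if dy > 0.0:
        sty, dty = 1, vs / dy
        ty = (oy + (iy + 1) * vs - sy) / dy
    elif dy < 0.0:
        sty, dty = -1, -vs / dy
        ty = (oy + iy * vs - sy) / dy
    else:
        sty, dty, ty = 0, big, big
    if dz > 0.0:
        stz, dtz = 1, vs / dz
        tz = (oz + (iz + 1) * vs - sz) / dz
    elif dz < 0.0:
        stz, dtz = -1, -vs / dz
        tz = (oz + iz * vs - sz) / dz
    else:
        stz, dtz, tz = 0, big, big

    t = tmin
    count = 0
    eps = 1e-12 * (tmax - tmin)
    max_steps = nx + ny + nz + _EXTRA
    for _ in range(max_steps):
        if tmax - t <= eps:
            break
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn > tmax:
            tn = tmax
        w = (tn - t) * seg_len
        if w > 0.0:
            idx_out[base + count] = ix * (ny * nz) + iy * nz + iz
            w_out[base + count] = w
            count += 1
        # advance every axis whose crossing coincides with tn (order x,y,z)
        if tx <= tn:
            ix += stx
            tx += dtx
        if ty <= tn:
            iy += sty
            ty += dty
        if tz <= tn:
            iz += stz
            tz += dtz
        t = tn
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
    return count


@njit(cache=True)
def trace_rays(sx, sy, sz, ex, ey, ez,
               ox, oy, oz, nx, ny, nz, vs):
    """Trace many segments from one source to per-ray endpoints.

    Returns a CSR triple (indptr, indices, weights) with one row per ray.
    """
    n_rays = ex.size
    max_per = nx + ny + nz + _EXTRA
    indptr = np.zeros(n_rays + 1, dtype=np.int64)
    idx = np.empty(n_rays * max_per, dtype=np.int32)
    w = np.empty(n_rays * max_per, dtype=np.float64)
    pos = 0
    for r in range(n_rays):
        cnt = _trace_one(sx, sy, sz, ex[r], ey[r], ez[r],
                         ox, oy, oz, nx, ny, nz, vs, idx, w, pos)
        pos += cnt
        indptr[r + 1] = pos
    return indptr, idx[:pos].copy(), w[:pos].copy()


@njit(cache=True)
def kaczmarz_sweep(x, data, indices, indptr, y):
    """One sequential ART sweep over all rows of a CSR system, in place.

    Each row update projects the current estimate onto that row's
    hyperplane; rows with zero squared norm are skipped.
    """
    m = y.size
    for i in range(m):
        a = indptr[i]
        b = indptr[i + 1]
        if a == b:
            continue
        dot = 0.0
        nrm = 0.0
        for p in range(a, b):
            v = data[p]
            dot += v * x[indices[p]]
            nrm += v * v
        if nrm <= 0.0:
            continue
        c = (y[i] - dot) / nrm
        for p in range(a, b):
            x[indices[p]] += c * data[p]
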