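"""Shared fixtures and independent oracles for the test suite.

The oracle functions deliberately use different algorithms from the
package (dense sampling instead of incremental traversal, global plane
sorting instead of stepping, explicit window loops instead of vectorized
moments, direct linear solves instead of iteration) so that agreement is
meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from dbtsim import PhantomGeometry, SimulationConfig, table1_config
from dbtsim.phantom import grid_origin

# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def table1_cfg() -> SimulationConfig:
    return table1_config()


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A scaled-down acquisition that keeps the full geometry structure:
    32x32x8 phantom, 48x48 detector, 7 views over the same 50-degree arc."""
    cfg = table1_config()
    cfg.source.n_projections = 7
    cfg.detector.n_u = cfg.detector.n_v = 48
    cfg.phantom.n_x = cfg.phantom.n_y = 32
    cfg.phantom.n_z = 8
    cfg.phantom.object_to_detector_distance = 30.0
    cfg.source.source_to_detector_distance = 90.0
    cfg.recon.layer_of_interest = 5
    cfg.recon.n_iterations = 5
    return cfg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)


# ---------------------------------------------------------------------------
# ray-tracing oracles


def clip_segment_to_box(src, dst, lo, hi):
    """Exact [tmin, tmax] of segment src->dst inside the axis box, or None."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    d = dst - src
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if d[a] != 0.0:
            t0 = (lo[a] - src[a]) / d[a]
            t1 = (hi[a] - src[a]) / d[a]
            t0, t1 = min(t0, t1), max(t0, t1)
            tmin, tmax = max(tmin, t0), min(tmax, t1)
        elif not lo[a] <= src[a] <= hi[a]:
            return None
    if tmax <= tmin:
        return None
    return tmin, tmax


def dense_ray_weights(src, dst, geom: PhantomGeometry, n_samples: int = 10_000):
    """Per-voxel path lengths by midpoint sampling of the in-grid segment.

    Returns a dict {linear voxel index: approximate length} and the in-grid
    segment length.
    """
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    o = grid_origin(geom)
    vs = geom.voxel_size
    hi = o + np.array([geom.n_x, geom.n_y, geom.n_z]) * vs
    clip = clip_segment_to_box(src, dst, o, hi)
    if clip is None:
        return {}, 0.0
    tmin, tmax = clip
    d = dst - src
    seg = float(np.linalg.norm(d)) * (tmax - tmin)
    ts = tmin + (tmax - tmin) * (np.arange(n_samples) + 0.5) / n_samples
    pts = src[None, :] + ts[:, None] * d[None, :]
    ijk = np.floor((pts - o[None, :]) / vs).astype(np.int64)
    np.clip(ijk[:, 0], 0, geom.n_x - 1, out=ijk[:, 0])
    np.clip(ijk[:, 1], 0, geom.n_y - 1, out=ijk[:, 1])
    np.clip(ijk[:, 2], 0, geom.n_z - 1, out=ijk[:, 2])
    lin = (ijk[:, 0] * geom.n_y + ijk[:, 1]) * geom.n_z + ijk[:, 2]
    idx, counts = np.unique(lin, return_counts=True)
    per = seg / n_samples
    return dict(zip(idx.tolist(), (counts * per).tolist())), seg


def sorted_crossing_weights(src, dst, geom: PhantomGeometry):
    """Exact per-voxel path lengths by globally sorting all voxel-plane
    crossing parameters (independent of the incremental traversal)."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    o = grid_origin(geom)
    vs = geom.voxel_size
    n = np.array([geom.n_x, geom.n_y, geom.n_z])
    hi = o + n * vs
    clip = clip_segment_to_box(src, dst, o, hi)
    if clip is None:
        return {}, 0.0
    tmin, tmax = clip
    d = dst - src
    ts = [np.array([tmin, tmax])]
    for a in range(3):
        if d[a] != 0.0:
            planes = o[a] + vs * np.arange(n[a] + 1)
            t = (planes - src[a]) / d[a]
            ts.append(t[(t > tmin) & (t < tmax)])
    t_all = np.unique(np.concatenate(ts))
    length = float(np.linalg.norm(d))
    out: dict[int, float] = {}
    for t0, t1 in zip(t_all[:-1], t_all[1:]):
        if t1 <= t0:
            continue
        mid = src + 0.5 * (t0 + t1) * d
        ijk = np.floor((mid - o) / vs).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= n):
            continue
        lin = (ijk[0] * n[1] + ijk[1]) * n[2] + ijk[2]
        out[lin] = out.get(lin, 0.0) + (t1 - t0) * length
    return out, length * (tmax - tmin)


def random_rays_through_grid(geom: PhantomGeometry, n: int,
                             rng: np.random.Generator):
    """Segments whose endpoints bracket the grid from above and below, with
    random lateral offsets, so most pass through the volume."""
    o = grid_origin(geom)
    vs = geom.voxel_size
    hi = o + np.array([geom.n_x, geom.n_y, geom.n_z]) * vs
    span = hi - o
    rays = []
    for _ in range(n):
        src = np.array([
            o[0] + span[0] * rng.uniform(-0.3, 1.3),
            o[1] + span[1] * rng.uniform(-0.3, 1.3),
            hi[2] + span[2] * rng.uniform(0.5, 2.0),
        ])
        dst = np.array([
            o[0] + span[0] * rng.uniform(-0.3, 1.3),
            o[1] + span[1] * rng.uniform(-0.3, 1.3),
            o[2] - span[2] * rng.uniform(0.5, 2.0),
        ])
        rays.append((src, dst))
    return rays


# ---------------------------------------------------------------------------
# linear-system oracle helpers


def random_consistent_system(n: int, rng: np.random.Generator):
    """A full-rank n x n system with controlled conditioning (singular
    values in [1, 2]) and a known exact solution."""
    q1, _ = np.linalg.qr(rng.standard_normal((n, n)))
    q2, _ = np.linalg.qr(rng.standard_normal((n, n)))
    a = q1 @ np.diag(rng.uniform(1.0, 2.0, n)) @ q2
    x_true = rng.standard_normal(n)
    return a, a @ x_true, x_true


def rays_from_matrix(a: np.ndarray, y: np.ndarray):
    """Wrap a dense system's rows as RayWeights measurement pairs."""
    from dbtsim import RayWeights

    idx = np.arange(a.shape[1])
    return [(RayWeights(idx, a[i]), float(y[i])) for i in range(a.shape[0])]


# ---------------------------------------------------------------------------
# SSIM oracle


def brute_force_ssim_map(x: np.ndarray, y: np.ndarray, k1=0.01, k2=0.03,
                         L=None, win=8) -> np.ndarray:
    """Window-by-window SSIM with explicit Python loops and population
    statistics; mirrors the documented conventions independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if L is None:
        ptp = max(x.max(), y.max()) - min(x.min(), y.min())
        L = ptp if ptp > 0 else 1.0
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    h = x.shape[0] - win + 1
    w = x.shape[1] - win + 1
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            xs = x[i:i + win, j:j + win].ravel()
            ys = y[i:i + win, j:j + win].ravel()
            mx, my = xs.mean(), ys.mean()
            vx = ((xs - mx) ** 2).mean()
            vy = ((ys - my) ** 2).mean()
            cov = ((xs - mx) * (ys - my)).mean()
            out[i, j] = (((2 * mx * my + c1) * (2 * cov + c2))
                         / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return out
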