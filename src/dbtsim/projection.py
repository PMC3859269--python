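"""Cone-beam forward projection for a step-and-shoot limited-angle scan.

The X-ray point source steps along a circular arc above the stationary
detector (z = 0 plane), stopping at equally spaced angles that include
both ends of the scan range.  At each stop, one ray is cast from the
source to the centre of every detector pixel, and the measurement is the
ray sum y_i = sum_j a_ij x_j, where a_ij is the exact length of the
intersection of ray i with voxel j (Siddon traversal).

The per-view system matrices are assembled once as sparse CSR matrices and
shared between projection and reconstruction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _siddon
from .config import DetectorGeometry, PhantomGeometry, SimulationConfig, validate_config
from .phantom import VoxelVolume, grid_origin

__all__ = [
    "SourcePosition",
    "RayWeights",
    "ProjectionSet",
    "source_positions",
    "detector_pixel_centers",
    "trace_ray",
    "system_matrix",
    "forward_project",
    "write_projections",
    "read_projections",
]


@dataclass(frozen=True)
class SourcePosition:
    """One stop of the source: angle (degrees from the central
    perpendicular) and world location on the arc."""

    angle: float
    location: tuple[float, float, float]


@dataclass
class RayWeights:
    """Sparse weights of one ray: voxel linear indices (C order over the
    (n_x, n_y, n_z) grid) and the matching intersection lengths."""

    indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def total_length(self) -> float:
        """Length of the segment inside the grid bounding box."""
        return float(self.weights.sum())


@dataclass
class ProjectionSet:
    """Stack of detector images, one per source position.

    ``images`` has shape (n_projections, n_u, n_v) with u along the scan
    direction.
    """

    images: np.ndarray
    angles: list[SourcePosition]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("ProjectionSet.images must be (n_projections, n_u, n_v)")
        if self.images.shape[0] != len(self.angles):
            raise ValueError("ProjectionSet: image count does not match angle count")

    @property
    def n_projections(self) -> int:
        return self.images.shape[0]


def source_positions(cfg: SimulationConfig) -> list[SourcePosition]:
    """Equally spaced source stops, inclusive of both scan-range endpoints.

    With n stops over [amin, amax] the step is (amax-amin)/(n-1); a single
    stop is placed at the midpoint.  The source moves in the x-z plane on
    the circle of radius ``source_to_detector_distance`` about the centre
    of the detector plane.
    """
    s = cfg.source
    if s.n_projections == 1:
        angles = np.array([0.5 * (s.scan_angle_min + s.scan_angle_max)])
    else:
        angles = np.linspace(s.scan_angle_min, s.scan_angle_max, s.n_projections)
    r = s.source_to_detector_distance
    out = []
    for a in angles:
        th = np.deg2rad(a)
        out.append(SourcePosition(float(a),
                                  (r * np.sin(th), 0.0, r * np.cos(th))))
    return out


def detector_pixel_centers(det: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """World x (per u index) and y (per v index) of detector pixel centres;
    the detector is centred on the origin of the z = 0 plane."""
    pitch = det.pixel_pitch
    xs = (np.arange(det.n_u) - 0.5 * det.n_u + 0.5) * pitch
    ys = (np.arange(det.n_v) - 0.5 * det.n_v + 0.5) * pitch
    return xs, ys


def trace_ray(p_source, p_detector_pixel, geom: PhantomGeometry) -> RayWeights:
    """Exact ray-voxel intersection lengths for one segment.

    Returns the voxels the segment crosses with their Euclidean
    intersection lengths; a ray that misses the grid yields empty weights.
    """
    src = np.asarray(p_source, dtype=np.float64)
    dst = np.asarray(p_detector_pixel, dtype=np.float64)
    if np.array_equal(src, dst):
        raise ValueError("ray endpoints must be distinct")
    o = grid_origin(geom)
    indptr, idx, w = _siddon.trace_rays(
        src[0], src[1], src[2],
        np.array([dst[0]]), np.array([dst[1]]), np.array([dst[2]]),
        o[0], o[1], o[2], geom.n_x, geom.n_y, geom.n_z, geom.voxel_size)
    return RayWeights(idx, w)


def system_matrix(cfg: SimulationConfig) -> list[sp.csr_matrix]:
    """Per-view sparse system matrices.

    Element (i, j) of the matrix for a view is the intersection length of
    the ray to detector pixel i (row-major over (u, v)) with voxel j
    (C-order linear index).  Shape: (n_u * n_v, n_x * n_y * n_z).
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    det, ph = cfg.detector, cfg.phantom
    o = grid_origin(ph)
    xs, ys = detector_pixel_centers(det)
    ex = np.repeat(xs, det.n_v)
    ey = np.tile(ys, det.n_u)
    ez = np.zeros_like(ex)
    n_vox = ph.n_x * ph.n_y * ph.n_z
    mats = []
    for pos in source_positions(cfg):
        sx, sy, sz = pos.location
        indptr, idx, w = _siddon.trace_rays(
            sx, sy, sz, ex, ey, ez,
            o[0], o[1], o[2], ph.n_x, ph.n_y, ph.n_z, ph.voxel_size)
        mats.append(sp.csr_matrix((w, idx, indptr),
                                  shape=(det.n_u * det.n_v, n_vox)))
    return mats


def forward_project(volume: VoxelVolume, cfg: SimulationConfig,
                    matrices: list[sp.csr_matrix] | None = None) -> ProjectionSet:
    """Ray-sum projections of a volume for every source position.

    Linear in the volume; nonnegative whenever the volume is nonnegative.
    ``matrices`` may carry precomputed :func:`system_matrix` output to
    avoid re-tracing.
    """
    ph, det = cfg.phantom, cfg.detector
    if volume.shape != (ph.n_x, ph.n_y, ph.n_z):
        raise ValueError(f"volume shape {volume.shape} does not match the "
                         f"configured phantom grid {(ph.n_x, ph.n_y, ph.n_z)}")
    if matrices is None:
        matrices = system_matrix(cfg)
    x = volume.data.ravel()
    positions = source_positions(cfg)
    images = np.empty((len(positions), det.n_u, det.n_v))
    for v, mat in enumerate(matrices):
        images[v] = (mat @ x).reshape(det.n_u, det.n_v)
    return ProjectionSet(images, positions)


# ---------------------------------------------------------------------------
# I/O: float32 multi-page TIFF (one page per angle) + JSON angle sidecar


def write_projections(ps: ProjectionSet, path: str | os.PathLike) -> None:
    import tifffile

    tifffile.imwrite(path, ps.images.astype(np.float32))
    with open(f"{path}.json", "w") as fh:
        json.dump({"angles": [p.angle for p in ps.angles],
                   "locations": [list(p.location) for p in ps.angles]}, fh)


def read_projections(path: str | os.PathLike) -> ProjectionSet:
    import tifffile

    images = np.asarray(tifffile.imread(path), dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    angles = [SourcePosition(a, tuple(loc))
              for a, loc in zip(meta["angles"], meta["locations"])]
    return ProjectionSet(images, angles)
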