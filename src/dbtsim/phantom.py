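"""Voxel phantoms built from geometric primitives.

A phantom is a regular grid of attenuation values.  It is assembled from a
list of simple solids (boxes, spheres, ellipsoids) with constant X-ray
absorption; a voxel belongs to a solid when its *centre* lies inside the
solid (no partial-volume antialiasing), and overlapping solids are resolved
by the painter's rule: the last primitive in the list wins.

Coordinates: primitive centres and half-extents are given in voxel units,
where the centre of voxel (i, j, k) sits at (i+0.5, j+0.5, k+0.5).  The k
axis runs from the detector toward the X-ray source, so "upper layers"
(large k) are closest to the source.

:func:`demo_phantom` builds the deterministic overlapping-tissue study
object: small high-absorption spheres in the upper layers directly above
larger low-absorption lesions, so that in a plain 2D projection the bright
spheres obscure the faint lesions underneath — the situation tomosynthesis
is designed to resolve.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle avoidance
    from .config import PhantomGeometry

__all__ = [
    "PrimitiveKind",
    "Primitive",
    "VoxelVolume",
    "rasterize_primitive",
    "build_phantom",
    "demo_phantom",
    "demo_layer_of_interest",
    "demo_roi",
    "write_volume_tiff",
    "read_volume_tiff",
    "write_volume_raw",
    "read_volume_raw",
]

logger = logging.getLogger(__name__)


class PrimitiveKind(str, Enum):
    BOX = "box"
    SPHERE = "sphere"
    ELLIPSOID = "ellipsoid"


@dataclass(frozen=True)
class Primitive:
    """A constant-intensity solid: box, sphere or ellipsoid.

    ``half_extents`` holds the box half-sides, the sphere radius replicated
    three times, or the ellipsoid semi-axes, all in voxel units.
    """

    kind: PrimitiveKind
    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    intensity: float

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "half_extents",
                           tuple(float(h) for h in self.half_extents))
        object.__setattr__(self, "intensity", float(self.intensity))

    @staticmethod
    def sphere(center, radius: float, intensity: float) -> "Primitive":
        r = float(radius)
        return Primitive(PrimitiveKind.SPHERE, tuple(center), (r, r, r), intensity)

    @staticmethod
    def box(center, half_extents, intensity: float) -> "Primitive":
        return Primitive(PrimitiveKind.BOX, tuple(center), tuple(half_extents), intensity)

    @staticmethod
    def ellipsoid(center, half_extents, intensity: float) -> "Primitive":
        return Primitive(PrimitiveKind.ELLIPSOID, tuple(center),
                         tuple(half_extents), intensity)

    def violations(self) -> list[str]:
        v = []
        if not all(h > 0 for h in self.half_extents):
            v.append("half_extents must be > 0 componentwise")
        if not self.intensity >= 0:
            v.append("intensity must be >= 0")
        return v


@dataclass
class VoxelVolume:
    """A 3D scalar field of attenuation values on a regular grid.

    ``data`` has shape (n_x, n_y, n_z); ``origin`` places the corner of
    voxel (0, 0, 0) in world coordinates, so the world position of the
    centre of voxel (i, j, k) is ``origin + (i+0.5, j+0.5, k+0.5) *
    voxel_size``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume.data must be 3-dimensional")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def layer(self, k: int) -> np.ndarray:
        """The (n_x, n_y) slice at layer index k."""
        return self.data[:, :, k]

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size, self.origin.copy())


def grid_origin(geom: "PhantomGeometry") -> np.ndarray:
    """World-coordinate corner of voxel (0,0,0): the grid is centred on the
    z axis with its mid-plane at ``object_to_detector_distance``."""
    vs = geom.voxel_size
    return np.array([
        -0.5 * geom.n_x * vs,
        -0.5 * geom.n_y * vs,
        geom.object_to_detector_distance - 0.5 * geom.n_z * vs,
    ])


def empty_volume(geom: "PhantomGeometry") -> VoxelVolume:
    return VoxelVolume(np.zeros((geom.n_x, geom.n_y, geom.n_z)),
                       geom.voxel_size, grid_origin(geom))


def _mask(prim: Primitive, geom: "PhantomGeometry") -> np.ndarray:
    ci = np.arange(geom.n_x)[:, None, None] + 0.5
    cj = np.arange(geom.n_y)[None, :, None] + 0.5
    ck = np.arange(geom.n_z)[None, None, :] + 0.5
    cx, cy, cz = prim.center
    hx, hy, hz = prim.half_extents
    if prim.kind is PrimitiveKind.BOX:
        return ((np.abs(ci - cx) <= hx)
                & (np.abs(cj - cy) <= hy)
                & (np.abs(ck - cz) <= hz))
    # sphere is an ellipsoid with equal semi-axes
    return (((ci - cx) / hx) ** 2
            + ((cj - cy) / hy) ** 2
            + ((ck - cz) / hz) ** 2) <= 1.0


def rasterize_primitive(prim: Primitive, geom: "PhantomGeometry") -> VoxelVolume:
    """Voxelize a single primitive: voxels whose centre lies inside the
    solid take its intensity, all others 0.

    A primitive lying entirely outside the grid yields an all-zero volume
    and a logged warning (not an error)."""
    bad = prim.violations()
    if bad:
        raise ValueError("invalid primitive: " + "; ".join(bad))
    vol = empty_volume(geom)
    m = _mask(prim, geom)
    if not m.any():
        logger.warning("primitive %s covers no voxel centre in grid %dx%dx%d",
                       prim.kind.value, geom.n_x, geom.n_y, geom.n_z)
    vol.data[m] = prim.intensity
    return vol


def build_phantom(primitives: list[Primitive], geom: "PhantomGeometry") -> VoxelVolume:
    """Rasterize a primitive list with painter's-rule overlap resolution:
    a voxel covered by several primitives takes the intensity of the LAST
    covering primitive in list order."""
    vol = empty_volume(geom)
    for prim in primitives:
        bad = prim.violations()
        if bad:
            raise ValueError("invalid primitive: " + "; ".join(bad))
        vol.data[_mask(prim, geom)] = prim.intensity
    return vol


def demo_layer_of_interest(n_z: int) -> int:
    """Layer index holding the low-absorption lesions of the demo phantom."""
    return int(round(0.65 * n_z))


def demo_primitives(geom: "PhantomGeometry") -> list[Primitive]:
    """Primitive list of the overlapping-tissue demo phantom (scaled to the
    grid): a faint tissue slab, three low-absorption lesions around the
    layer of interest, and three small bright spheres in the upper layers
    vertically above the lesions."""
    nx, ny, nz = geom.n_x, geom.n_y, geom.n_z
    if nx < 32 or ny < 32 or nz < 8:
        raise ValueError("demo phantom needs a grid of at least 32x32x8 voxels")
    sites = [(0.30, 0.30), (0.52, 0.68), (0.72, 0.40)]
    lesion_he = (0.10 * nx, 0.08 * ny, max(1.0, 0.08 * nz))
    sphere_r = max(0.9, min(0.035 * nx, 0.12 * nz))
    prims = [
        Primitive.box((0.5 * nx, 0.5 * ny, 0.45 * nz),
                      (0.35 * nx, 0.35 * ny, 0.28 * nz), 0.05),
    ]
    for fx, fy in sites:
        prims.append(Primitive.ellipsoid((fx * nx, fy * ny, 0.65 * nz),
                                         lesion_he, 0.3))
    for fx, fy in sites:
        prims.append(Primitive.sphere((fx * nx, fy * ny, 0.85 * nz),
                                      sphere_r, 1.0))
    return prims


def demo_phantom(geom: "PhantomGeometry") -> tuple[VoxelVolume, list[Primitive]]:
    """Deterministic overlapping-tissue study phantom.

    High-absorption spheres sit in the upper layers directly above
    low-absorption lesions near :func:`demo_layer_of_interest`, so that the
    spheres obscure the lesions along the central projection direction.
    Returns the rasterized volume together with its generating primitives.
    """
    prims = demo_primitives(geom)
    return build_phantom(prims, geom), prims


def demo_roi(geom: "PhantomGeometry"):
    """Signal/background masks on the demo layer of interest, for CNR.

    The signal region is the core of the first lesion; the background is an
    equally sized patch of plain slab tissue away from all lesions."""
    nx, ny = geom.n_x, geom.n_y
    ii = np.arange(nx)[:, None] + 0.5
    jj = np.arange(ny)[None, :] + 0.5
    hx, hy = 0.05 * nx, 0.04 * ny
    signal = (np.abs(ii - 0.30 * nx) <= hx) & (np.abs(jj - 0.30 * ny) <= hy)
    background = (np.abs(ii - 0.50 * nx) <= hx) & (np.abs(jj - 0.30 * ny) <= hy)
    return signal, background


# ---------------------------------------------------------------------------
# file I/O: float32 multi-page TIFF (one page per layer) and raw + JSON


def write_volume_tiff(vol: VoxelVolume, path: str | os.PathLike) -> None:
    import tifffile

    pages = np.ascontiguousarray(vol.data.transpose(2, 0, 1).astype(np.float32))
    tifffile.imwrite(path, pages)


def read_volume_tiff(path: str | os.PathLike, voxel_size: float = 1.0,
                     origin=(0.0, 0.0, 0.0)) -> VoxelVolume:
    import tifffile

    pages = np.asarray(tifffile.imread(path), dtype=np.float64)
    if pages.ndim == 2:
        pages = pages[None]
    return VoxelVolume(pages.transpose(1, 2, 0), voxel_size, np.asarray(origin))


def write_volume_raw(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Raw little-endian float32 (C order, shape (n_x, n_y, n_z)) with a
    JSON sidecar ``<path>.json`` recording shape, voxel size and origin."""
    vol.data.astype("<f4").tofile(path)
    with open(f"{path}.json", "w") as fh:
        json.dump({"shape": list(vol.shape), "voxel_size": vol.voxel_size,
                   "origin": list(map(float, vol.origin))}, fh)


def read_volume_raw(path: str | os.PathLike) -> VoxelVolume:
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    data = np.fromfile(path, dtype="<f4").astype(np.float64)
    data = data.reshape(tuple(meta["shape"]))
    return VoxelVolume(data, meta["voxel_size"], np.asarray(meta["origin"]))
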