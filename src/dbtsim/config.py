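"""System configuration for the tomosynthesis simulator.

A :class:`SimulationConfig` fully describes one simulated acquisition and
reconstruction: the X-ray source arc, the flat-panel detector, the voxel
grid of the phantom, the reconstruction method and its parameters, and the
lists of geometric primitives making up the true phantom and the optional
initial guess.

All lengths are expressed in detector-pixel units: the detector pixel pitch
and the voxel edge both default to 1 unit, so e.g. a source-to-detector
distance of 300 means 300 pixel widths.

Configurations are serialized to a small XML dialect (see
:func:`load_config` / :func:`save_config`).
"""

from __future__ import annotations

import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum

from .phantom import Primitive, PrimitiveKind

__all__ = [
    "ReconMethod",
    "SourceGeometry",
    "DetectorGeometry",
    "PhantomGeometry",
    "ReconSettings",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "validate_config",
    "table1_config",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration violates one of its invariants."""


class ReconMethod(str, Enum):
    """Reconstruction algorithms offered by the simulator."""

    ART = "ART"
    SART = "SART"
    ART_TV3D = "ART_TV3D"
    SART_TV3D = "SART_TV3D"
    PICCS = "PICCS"

    @property
    def uses_tv(self) -> bool:
        return self in (ReconMethod.ART_TV3D, ReconMethod.SART_TV3D, ReconMethod.PICCS)

    @property
    def uses_sart(self) -> bool:
        return self in (ReconMethod.SART, ReconMethod.SART_TV3D)


@dataclass
class SourceGeometry:
    """X-ray point source travelling a circular arc above the detector.

    The arc is centred on the middle of the detector plane; ``angle`` is
    measured in degrees from the central perpendicular, so angle 0 places
    the source straight above the detector centre.
    """

    source_to_detector_distance: float = 300.0
    scan_angle_min: float = -25.0
    scan_angle_max: float = 25.0
    n_projections: int = 11


@dataclass
class DetectorGeometry:
    """Stationary flat-panel detector in the z = 0 plane.

    ``n_u`` pixels run along the scan (x) direction, ``n_v`` along y.
    """

    n_u: int = 160
    n_v: int = 160
    pixel_pitch: float = 1.0


@dataclass
class PhantomGeometry:
    """Regular voxel grid holding the object, centred above the detector.

    ``object_to_detector_distance`` locates the grid centre on the z axis;
    layer index k grows from the detector toward the source, so "upper
    layers" are those closest to the source.
    """

    n_x: int = 128
    n_y: int = 128
    n_z: int = 16
    object_to_detector_distance: float = 100.0
    voxel_size: float = 1.0


@dataclass
class ReconSettings:
    """Parameters of the iterative reconstruction loop.

    ``n_iterations`` (NOI) counts outer iterations, each consisting of one
    full ART sweep or SART pass followed, for the TV-regularized methods,
    by a number of total-variation descent steps on the whole volume.
    ``layer_of_interest`` (LOI, 0-based) selects the slice used for display
    and slice-wise metrics.  ``omega`` is the SART relaxation factor,
    ``tv_weight`` scales the TV descent step, ``piccs_alpha`` blends the
    prior-image and plain TV terms of the PICCS objective, and ``epsilon``
    is the residual-norm threshold of the outer ``while`` loop (0 means
    "run exactly NOI iterations").  ``tv_step_size`` of ``None`` selects an
    adaptive step of 0.2x the mean absolute voxel change of the preceding
    data-consistency sweep.
    """

    method: ReconMethod = ReconMethod.ART
    n_iterations: int = 15
    layer_of_interest: int = 10
    omega: float = 1.0
    tv_weight: float = 0.8
    piccs_alpha: float = 0.0
    epsilon: float = 0.0
    tv_steps: int = 20
    tv_step_size: float | None = None
    clamp_nonnegative: bool = False


@dataclass
class SimulationConfig:
    """Complete description of one simulated acquisition + reconstruction."""

    source: SourceGeometry = field(default_factory=SourceGeometry)
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)
    phantom: PhantomGeometry = field(default_factory=PhantomGeometry)
    recon: ReconSettings = field(default_factory=ReconSettings)
    primitives: list[Primitive] = field(default_factory=list)
    initial_primitives: list[Primitive] = field(default_factory=list)


def table1_config() -> SimulationConfig:
    """The demo acquisition geometry: 300/100 pixel distances, a 50 degree
    arc (-25 to +25) with 11 views, a 160x160 detector and a 128x128x16
    phantom grid, reconstructed with 15 outer iterations at layer 10."""
    return SimulationConfig()


# ---------------------------------------------------------------------------
# validation

def validate_config(cfg: SimulationConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Never raises: every rule is reported as a string naming the offending
    field, so callers can show all problems at once.
    """
    v: list[str] = []
    s, d, p, r = cfg.source, cfg.detector, cfg.phantom, cfg.recon

    if not s.source_to_detector_distance > 0:
        v.append("source.source_to_detector_distance must be > 0")
    if not s.scan_angle_min < s.scan_angle_max:
        v.append("source.scan_angle_min must be < source.scan_angle_max")
    if not s.n_projections >= 1:
        v.append("source.n_projections must be >= 1")

    if not d.n_u >= 1:
        v.append("detector.n_u must be >= 1")
    if not d.n_v >= 1:
        v.append("detector.n_v must be >= 1")
    if not d.pixel_pitch > 0:
        v.append("detector.pixel_pitch must be > 0")

    for name in ("n_x", "n_y", "n_z"):
        if not getattr(p, name) >= 1:
            v.append(f"phantom.{name} must be >= 1")
    if not p.object_to_detector_distance >= 0:
        v.append("phantom.object_to_detector_distance must be >= 0")
    if not p.voxel_size > 0:
        v.append("phantom.voxel_size must be > 0")

    if not isinstance(r.method, ReconMethod):
        v.append(f"recon.method unknown: {r.method!r}")
    if not r.n_iterations >= 0:
        v.append("recon.n_iterations must be >= 0")
    if not 0 < r.omega < 2:
        v.append("recon.omega must lie in (0, 2)")
    if not 0 <= r.tv_weight <= 1:
        v.append("recon.tv_weight must lie in [0, 1]")
    if not 0 <= r.piccs_alpha <= 1:
        v.append("recon.piccs_alpha must lie in [0, 1]")
    if not r.epsilon >= 0:
        v.append("recon.epsilon must be >= 0")
    if not 0 <= r.layer_of_interest < p.n_z:
        v.append("recon.layer_of_interest must lie in [0, phantom.n_z)")
    if not r.tv_steps >= 0:
        v.append("recon.tv_steps must be >= 0")
    if r.tv_step_size is not None and not r.tv_step_size > 0:
        v.append("recon.tv_step_size must be > 0 when given")

    for label, prims in (("primitives", cfg.primitives),
                         ("initial_primitives", cfg.initial_primitives)):
        for i, prim in enumerate(prims):
            v.extend(f"{label}[{i}]: {msg}" for msg in prim.violations())
    return v


def _require_valid(cfg: SimulationConfig) -> SimulationConfig:
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return cfg


# ---------------------------------------------------------------------------
# XML serialization
#
# Layout:
#   <simulation>
#     <xraysource distance=".." angle_min=".." angle_max=".." n_projections=".."/>
#     <detector nu=".." nv=".." pitch=".."/>
#     <phantom nx=".." ny=".." nz=".." object_distance=".." voxel_size="..">
#       <object kind="sphere" center="x,y,z" half_extents="a,b,c" intensity=".."/>
#       <initial_object .../>
#     </phantom>
#     <reconstruction method=".." noi=".." loi=".." omega=".." tv_weight=".."
#                     alpha=".." epsilon=".." tv_steps=".." tv_step_size=".."
#                     clamp_nonnegative="0|1"/>
#   </simulation>

_F = float
_I = int


def _fmt(x) -> str:
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _vec(vals) -> str:
    return ",".join(repr(float(c)) for c in vals)


def _parse_vec(s: str, where: str):
    parts = [p.strip() for p in s.split(",")]
    if len(parts) != 3:
        raise ConfigError(f"{where}: expected 3 comma-separated numbers, got {s!r}")
    return tuple(float(p) for p in parts)


def _get(elem: ET.Element, attr: str, conv, default, where: str):
    raw = elem.get(attr)
    if raw is None:
        return default
    try:
        return conv(raw)
    except ValueError as exc:
        raise ConfigError(f"{where}@{attr}: cannot parse {raw!r}") from exc


_KNOWN = {
    "simulation": (),
    "xraysource": ("distance", "angle_min", "angle_max", "n_projections"),
    "detector": ("nu", "nv", "pitch"),
    "phantom": ("nx", "ny", "nz", "object_distance", "voxel_size"),
    "object": ("kind", "center", "half_extents", "intensity"),
    "initial_object": ("kind", "center", "half_extents", "intensity"),
    "reconstruction": ("method", "noi", "loi", "omega", "tv_weight", "alpha",
                       "epsilon", "tv_steps", "tv_step_size", "clamp_nonnegative"),
}


def _warn_unknown(elem: ET.Element) -> None:
    if elem.tag not in _KNOWN:
        logger.warning("ignoring unknown XML tag <%s>", elem.tag)
        return
    for attr in elem.attrib:
        if attr not in _KNOWN[elem.tag]:
            logger.warning("ignoring unknown attribute %r on <%s>", attr, elem.tag)


def _parse_primitive(elem: ET.Element) -> Primitive:
    kind = elem.get("kind", "sphere")
    try:
        pkind = PrimitiveKind(kind)
    except ValueError as exc:
        raise ConfigError(f"<{elem.tag}>@kind: unknown primitive kind {kind!r}") from exc
    center = _parse_vec(elem.get("center", "0,0,0"), f"<{elem.tag}>@center")
    he = _parse_vec(elem.get("half_extents", "1,1,1"), f"<{elem.tag}>@half_extents")
    intensity = _get(elem, "intensity", float, 1.0, f"<{elem.tag}>")
    return Primitive(kind=pkind, center=center, half_extents=he, intensity=intensity)


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Read and validate a simulation configuration from an XML file.

    Unknown tags and attributes are ignored with a logged warning; missing
    optional attributes take the documented defaults.  Raises
    :class:`FileNotFoundError` for a missing file, :class:`ConfigError`
    (with the line number) for malformed XML, and :class:`ConfigError`
    naming the field for invariant violations.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ConfigError(f"malformed XML in {path} at line {line}, column {col}: "
                          f"{exc}") from exc
    root = tree.getroot()
    if root.tag != "simulation":
        raise ConfigError(f"root element must be <simulation>, got <{root.tag}>")

    cfg = SimulationConfig()
    for elem in root.iter():
        _warn_unknown(elem)

    src = root.find("xraysource")
    if src is not None:
        cfg.source = SourceGeometry(
            source_to_detector_distance=_get(src, "distance", _F, 300.0, "<xraysource>"),
            scan_angle_min=_get(src, "angle_min", _F, -25.0, "<xraysource>"),
            scan_angle_max=_get(src, "angle_max", _F, 25.0, "<xraysource>"),
            n_projections=_get(src, "n_projections", _I, 11, "<xraysource>"),
        )
    det = root.find("detector")
    if det is not None:
        cfg.detector = DetectorGeometry(
            n_u=_get(det, "nu", _I, 160, "<detector>"),
            n_v=_get(det, "nv", _I, 160, "<detector>"),
            pixel_pitch=_get(det, "pitch", _F, 1.0, "<detector>"),
        )
    ph = root.find("phantom")
    if ph is not None:
        cfg.phantom = PhantomGeometry(
            n_x=_get(ph, "nx", _I, 128, "<phantom>"),
            n_y=_get(ph, "ny", _I, 128, "<phantom>"),
            n_z=_get(ph, "nz", _I, 16, "<phantom>"),
            object_to_detector_distance=_get(ph, "object_distance", _F, 100.0, "<phantom>"),
            voxel_size=_get(ph, "voxel_size", _F, 1.0, "<phantom>"),
        )
        cfg.primitives = [_parse_primitive(e) for e in ph.findall("object")]
        cfg.initial_primitives = [_parse_primitive(e) for e in ph.findall("initial_object")]
    rec = root.find("reconstruction")
    if rec is not None:
        method_name = rec.get("method", "ART")
        try:
            method = ReconMethod(method_name)
        except ValueError as exc:
            raise ConfigError(f"<reconstruction>@method: unknown method "
                              f"{method_name!r}") from exc
        tvs = rec.get("tv_step_size")
        cfg.recon = ReconSettings(
            method=method,
            n_iterations=_get(rec, "noi", _I, 15, "<reconstruction>"),
            layer_of_interest=_get(rec, "loi", _I, 10, "<reconstruction>"),
            omega=_get(rec, "omega", _F, 1.0, "<reconstruction>"),
            tv_weight=_get(rec, "tv_weight", _F, 0.8, "<reconstruction>"),
            piccs_alpha=_get(rec, "alpha", _F, 0.0, "<reconstruction>"),
            epsilon=_get(rec, "epsilon", _F, 0.0, "<reconstruction>"),
            tv_steps=_get(rec, "tv_steps", _I, 20, "<reconstruction>"),
            tv_step_size=float(tvs) if tvs is not None else None,
            clamp_nonnegative=bool(_get(rec, "clamp_nonnegative", _I, 0,
                                        "<reconstruction>")),
        )
    return _require_valid(cfg)


def _prim_elem(parent: ET.Element, tag: str, prim: Primitive) -> None:
    ET.SubElement(parent, tag, {
        "kind": prim.kind.value,
        "center": _vec(prim.center),
        "half_extents": _vec(prim.half_extents),
        "intensity": _fmt(float(prim.intensity)),
    })


def save_config(cfg: SimulationConfig, path: str | os.PathLike) -> None:
    """Write ``cfg`` as XML such that :func:`load_config` reproduces it."""
    _require_valid(cfg)
    root = ET.Element("simulation")
    s, d, p, r = cfg.source, cfg.detector, cfg.phantom, cfg.recon
    ET.SubElement(root, "xraysource", {
        "distance": _fmt(float(s.source_to_detector_distance)),
        "angle_min": _fmt(float(s.scan_angle_min)),
        "angle_max": _fmt(float(s.scan_angle_max)),
        "n_projections": _fmt(int(s.n_projections)),
    })
    ET.SubElement(root, "detector", {
        "nu": _fmt(int(d.n_u)), "nv": _fmt(int(d.n_v)),
        "pitch": _fmt(float(d.pixel_pitch)),
    })
    ph = ET.SubElement(root, "phantom", {
        "nx": _fmt(int(p.n_x)), "ny": _fmt(int(p.n_y)), "nz": _fmt(int(p.n_z)),
        "object_distance": _fmt(float(p.object_to_detector_distance)),
        "voxel_size": _fmt(float(p.voxel_size)),
    })
    for prim in cfg.primitives:
        _prim_elem(ph, "object", prim)
    for prim in cfg.initial_primitives:
        _prim_elem(ph, "initial_object", prim)
    rec_attrs = {
        "method": r.method.value,
        "noi": _fmt(int(r.n_iterations)),
        "loi": _fmt(int(r.layer_of_interest)),
        "omega": _fmt(float(r.omega)),
        "tv_weight": _fmt(float(r.tv_weight)),
        "alpha": _fmt(float(r.piccs_alpha)),
        "epsilon": _fmt(float(r.epsilon)),
        "tv_steps": _fmt(int(r.tv_steps)),
        "clamp_nonnegative": _fmt(bool(r.clamp_nonnegative)),
    }
    if r.tv_step_size is not None:
        rec_attrs["tv_step_size"] = _fmt(float(r.tv_step_size))
    ET.SubElement(root, "reconstruction", rec_attrs)

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)
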