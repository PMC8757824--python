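"""Parametric stent-graft device models.

Z-stent rings are built as zig-zag wire paths on a (possibly tapering)
cylinder: 2*n_peaks straight limbs joined by rounded apices, meshed coarsely
on the limbs and finely in the high-curvature apex regions. The same specs
drive the Stage-1 centerline reduced model (one compliant beam per stent,
translation-coupled to its neighbours) and the Stage-2 strut lattices
(316L steel wire, Euler-Bernoulli corotational beams).

Device coordinates: z along the device axis (proximal -> distal), x toward
the 0-rad generatrix, angles right-handed about +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .fem import BeamAssembly, MaterialSection, STEEL_316L, frame_from_axis


class InvalidSpecError(ValueError):
    pass


#: Stage-1 centerline material (robustness-tuned, deliberately soft).
CENTERLINE_E = 10.0
CENTERLINE_NU = 0.3
#: Stage-1 centerline beam section diameter (mm); compliant relative to the
#: image-ray springs and wall contact so the single-view evidence dominates.
CENTERLINE_SECTION_DIAMETER = 2.0
APEX_ROUNDING_FACTOR = 2.0  # apex arc radius = factor * wire diameter


@dataclass(frozen=True)
class StentSpec:
    """One Z-stent ring: geometry of the zig-zag wire."""

    n_peaks: int
    height: float
    diameter_proximal: float
    diameter_distal: float
    wire_diameter: float = 0.125
    axial_position: float = 0.0  # ring center along the device axis (mm)

    def __post_init__(self):
        if self.n_peaks < 3:
            raise InvalidSpecError("a Z-stent needs at least 3 peaks")
        for nm in ("height", "diameter_proximal", "diameter_distal", "wire_diameter"):
            if not getattr(self, nm) > 0:
                raise InvalidSpecError(f"{nm} must be positive")
        if self.wire_diameter >= self.height:
            raise InvalidSpecError("wire diameter must be smaller than stent height")

    def radius_at(self, z_local: float) -> float:
        """Nominal wire-centerline radius at local z in [-h/2, h/2]."""
        t = (z_local + self.height / 2.0) / self.height
        return 0.5 * (
            self.diameter_proximal + t * (self.diameter_distal - self.diameter_proximal)
        )


@dataclass
class Fenestration:
    stent_index: int
    angle: float  # rad about +z
    axial_offset: float  # mm from the host stent center
    radius: float  # mm


@dataclass
class GraftSpec:
    """Full device: ordered stents plus fenestrations and radiopaque markers.

    ``markers`` are (host stent index, xyz point in device coordinates);
    they ride rigidly with their host stent through every later transform.
    """

    stents: list[StentSpec]
    inter_stent_gap: float = 2.0
    fenestrations: list[Fenestration] = field(default_factory=list)
    markers: list[tuple[int, np.ndarray]] = field(default_factory=list)
    launcher_diameter: float = 6.0
    name: str = "device"

    def __post_init__(self):
        if not self.stents:
            raise InvalidSpecError("graft must contain at least one stent")
        zs = [s.axial_position for s in self.stents]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise InvalidSpecError("stents must be ordered by axial position")
        for a, b in zip(self.stents, self.stents[1:]):
            if a.axial_position + a.height / 2 > b.axial_position - b.height / 2 + 1e-9:
                raise InvalidSpecError("stents overlap axially")
        for f in self.fenestrations:
            if not 0 <= f.stent_index < len(self.stents):
                raise InvalidSpecError("fenestration references a missing stent")
            if f.radius >= self.stents[f.stent_index].height:
                raise InvalidSpecError("fenestration radius exceeds stent height")
        marked = {i for i, _ in self.markers}
        for f in self.fenestrations:
            if f.stent_index not in marked:
                raise InvalidSpecError(
                    "every fenestrated stent must carry at least one radiopaque marker"
                )

    @property
    def n_stents(self) -> int:
        return len(self.stents)


def auto_markers(
    stents: list[StentSpec], fenestrations: list[Fenestration]
) -> list[tuple[int, np.ndarray]]:
    """Two markers per fenestration: rim centroid and rim-top point."""
    markers = []
    for f in fenestrations:
        s = stents[f.stent_index]
        z = s.axial_position + f.axial_offset
        R = s.radius_at(f.axial_offset)
        c = np.array([R * math.cos(f.angle), R * math.sin(f.angle), z])
        markers.append((f.stent_index, c))
        markers.append((f.stent_index, c + np.array([0.0, 0.0, f.radius])))
    return markers


# ----------------------------------------------------------------------
# Z-stent strut mesh
# ----------------------------------------------------------------------


@dataclass
class StentMesh:
    """Beam discretization + point cloud of one stent, in device coordinates.

    ``cloud`` samples the wire path at the fine mesh size; ``V`` is the same
    cloud expressed from the 3D barycenter ``barycenter`` in the stent local
    frame (frame columns = local axes in device coordinates, axis 2 = device
    axis).
    """

    spec: StentSpec
    assembly: BeamAssembly
    cloud: np.ndarray
    barycenter: np.ndarray
    frame: np.ndarray
    element_tags: list[str]
    node_z_local: np.ndarray

    @property
    def V(self) -> np.ndarray:
        return (self.cloud - self.barycenter) @ self.frame

    def _run_count(self, tag: str) -> int:
        tags = self.element_tags
        return sum(
            1
            for k, t in enumerate(tags)
            if t == tag and tags[k - 1] != tag  # circular: k-1 wraps at 0
        )

    @property
    def limb_count(self) -> int:
        return self._run_count("limb")

    @property
    def apex_count(self) -> int:
        return self._run_count("apex")


def _zigzag_path(spec: StentSpec, mesh_sizes: tuple[float, float]):
    """Sample the zig-zag in the developed (s, z) plane.

    Returns per-sample (s, z, tag) polyline points for one full ring, where
    s is the circumferential arc coordinate at the mean radius.
    """
    coarse, fine = mesh_sizes
    if not (coarse >= fine > 0):
        raise InvalidSpecError("mesh sizes must satisfy coarse >= fine > 0")
    n = spec.n_peaks
    h = spec.height
    Rm = 0.25 * (spec.diameter_proximal + spec.diameter_distal)
    C = 2.0 * math.pi * Rm
    half_pitch = C / (2 * n)
    ra = APEX_ROUNDING_FACTOR * spec.wire_diameter
    gamma = math.atan2(half_pitch, h)  # limb angle from the device axis
    trim = ra / math.tan(gamma) if math.tan(gamma) > 0 else math.inf
    limb_len = math.hypot(half_pitch, h)
    if 2.0 * trim >= limb_len or ra >= h / 2:
        raise InvalidSpecError("stent height too small for the peak count")

    apex_s = np.arange(2 * n) * half_pitch
    apex_z = np.where(np.arange(2 * n) % 2 == 0, h / 2.0, -h / 2.0)
    pts: list[tuple[float, float, str]] = []
    for k in range(2 * n):
        a = np.array([apex_s[k], apex_z[k]])
        nxt = np.array([apex_s[(k + 1) % (2 * n)], apex_z[(k + 1) % (2 * n)]])
        if k == 2 * n - 1:
            nxt = np.array([apex_s[k] + half_pitch, -apex_z[k]])
        prv = np.array([apex_s[k] - half_pitch, -apex_z[k]])
        u_in = (a - prv) / np.linalg.norm(a - prv)
        u_out = (nxt - a) / np.linalg.norm(nxt - a)
        t_in = a - trim * u_in
        t_out = a + trim * u_out
        # circular arc center on the interior bisector
        bis = (u_out - u_in)
        bis /= np.linalg.norm(bis)
        center = a + (ra / math.sin(gamma)) * bis
        v0 = t_in - center
        v1 = t_out - center
        ang0 = math.atan2(v0[1], v0[0])
        ang1 = math.atan2(v1[1], v1[0])
        sweep = (ang1 - ang0 + math.pi) % (2 * math.pi) - math.pi
        n_arc = max(2, int(math.ceil(abs(sweep) * ra / fine)))
        for t in np.linspace(0.0, 1.0, n_arc + 1)[:-1]:
            ang = ang0 + sweep * t
            p = center + ra * np.array([math.cos(ang), math.sin(ang)])
            pts.append((p[0], p[1], "apex"))
        # straight limb to the next apex's entry tangent point
        l_start = t_out
        l_end = nxt - trim * u_out
        seg = np.linalg.norm(l_end - l_start)
        n_limb = max(1, int(math.ceil(seg / coarse)))
        for t in np.linspace(0.0, 1.0, n_limb + 1)[:-1]:
            p = l_start + (l_end - l_start) * t
            pts.append((p[0], p[1], "limb"))
    return pts, Rm


def _develop_to_3d(spec: StentSpec, s: np.ndarray, z: np.ndarray, Rm: float) -> np.ndarray:
    theta = s / Rm
    R = np.array([spec.radius_at(zz) for zz in np.atleast_1d(z)])
    return np.column_stack([R * np.cos(theta), R * np.sin(theta), z])


def build_zstent_mesh(
    spec: StentSpec, mesh_sizes: tuple[float, float] = (2.0, 0.1)
) -> StentMesh:
    """Discretize one Z-stent into corotational beams and a point cloud.

    Limbs are meshed at the coarse size and the rounded apices at the fine
    size; the point cloud resamples the whole wire path at a spacing no
    larger than the fine size (needed later by the point-cloud metric and
    by the rotation-recovery projections).
    """
    coarse, fine = mesh_sizes
    pts, Rm = _zigzag_path(spec, mesh_sizes)
    s = np.array([p[0] for p in pts])
    z = np.array([p[1] for p in pts])
    tags = [p[2] for p in pts]
    xyz = _develop_to_3d(spec, s, z, Rm)
    xyz[:, 2] += spec.axial_position

    section = MaterialSection.circular(
        STEEL_316L["E"], STEEL_316L["nu"], spec.wire_diameter, shear_factor=None
    )
    a = BeamAssembly()
    for p in xyz:
        a.add_node(p)
    n_nodes = len(xyz)
    el_tags = []
    for k in range(n_nodes):
        j = (k + 1) % n_nodes
        a.add_element(k, j, section, tag=tags[k])
        el_tags.append(tags[k])

    # dense cloud along the developed path at <= fine spacing
    s_closed = np.append(s, s[0] + 2 * math.pi * Rm)
    z_closed = np.append(z, z[0])
    cloud_pts = []
    for k in range(n_nodes):
        seg = math.hypot(s_closed[k + 1] - s_closed[k], z_closed[k + 1] - z_closed[k])
        m = max(1, int(math.ceil(seg / fine)))
        for t in np.linspace(0.0, 1.0, m + 1)[:-1]:
            cloud_pts.append(
                (
                    s_closed[k] + t * (s_closed[k + 1] - s_closed[k]),
                    z_closed[k] + t * (z_closed[k + 1] - z_closed[k]),
                )
            )
    cs = np.array([c[0] for c in cloud_pts])
    cz = np.array([c[1] for c in cloud_pts])
    cloud = _develop_to_3d(spec, cs, cz, Rm)
    cloud[:, 2] += spec.axial_position
    barycenter = cloud.mean(axis=0)
    return StentMesh(
        spec=spec,
        assembly=a,
        cloud=cloud,
        barycenter=barycenter,
        frame=np.eye(3),
        element_tags=el_tags,
        node_z_local=z.copy(),
    )


# ----------------------------------------------------------------------
# Stage-1 centerline reduced model
# ----------------------------------------------------------------------


def build_centerline_assembly(graft: GraftSpec) -> BeamAssembly:
    """One compliant beam per stent along z, neighbours translation-coupled.

    Initialized straight and fully deployed. Each pair of consecutive beams
    shares a junction position through a joint that transmits force but no
    moment (the fabric sews stents together without rotational stiffness).
    """
    section = MaterialSection.circular(
        CENTERLINE_E, CENTERLINE_NU, CENTERLINE_SECTION_DIAMETER, shear_factor=None
    )
    n = graft.n_stents
    bounds = np.empty(n + 1)
    s0, sl = graft.stents[0], graft.stents[-1]
    bounds[0] = s0.axial_position - s0.height / 2 - graft.inter_stent_gap / 2
    bounds[n] = sl.axial_position + sl.height / 2 + graft.inter_stent_gap / 2
    for i in range(1, n):
        a, b = graft.stents[i - 1], graft.stents[i]
        bounds[i] = 0.5 * (a.axial_position + a.height / 2 + b.axial_position - b.height / 2)

    asm = BeamAssembly()
    for i in range(n):
        na = asm.add_node([0.0, 0.0, bounds[i]])
        nb = asm.add_node([0.0, 0.0, bounds[i + 1]])
        asm.add_element(na, nb, section, tag=f"stent{i}")
        if i > 0:
            asm.add_joint(2 * i - 1, 2 * i)
    return asm


# ----------------------------------------------------------------------
# Fenestrations and markers
# ----------------------------------------------------------------------


@dataclass
class FenestrationPoints:
    stent_index: int
    centroid: np.ndarray
    rim: np.ndarray  # (m, 3) device coordinates


def place_fenestration_points(
    graft: GraftSpec, n_rim: int = 36
) -> tuple[list[FenestrationPoints], list[tuple[int, np.ndarray]]]:
    """Discretize fenestration rims and collect marker points.

    Each rim is a circle of the fenestration radius in the plane tangent to
    the stent cylinder at the fenestration centroid, so the centroid lies
    exactly on the surface; rims and markers are rigidly co-transformed with
    their host stent by every later pose change.
    """
    fens = []
    for f in graft.fenestrations:
        s = graft.stents[f.stent_index]
        z = s.axial_position + f.axial_offset
        R = s.radius_at(f.axial_offset)
        c = np.array([R * math.cos(f.angle), R * math.sin(f.angle), z])
        tangential = np.array([-math.sin(f.angle), math.cos(f.angle), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        t = np.linspace(0.0, 2 * math.pi, n_rim, endpoint=False)
        rim = c + f.radius * (np.outer(np.cos(t), tangential) + np.outer(np.sin(t), axial))
        fens.append(FenestrationPoints(f.stent_index, c, rim))
    return fens, [(i, np.asarray(p, float)) for i, p in graft.markers]


def pose_assembly(mesh: "StentMesh", center, triad, phi: float) -> BeamAssembly:
    """Rigidly posed deep copy of a stent's beam assembly (world coords).

    All node rotations are set to the same rigid rotation, so the posed
    assembly is stress-free by construction.
    """
    import copy

    from scipy.spatial.transform import Rotation

    cp, sp = math.cos(phi), math.sin(phi)
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    R = np.asarray(triad) @ Rz
    rv = Rotation.from_matrix(R).as_rotvec()
    device_center = np.array([0.0, 0.0, mesh.spec.axial_position])
    asm = copy.deepcopy(mesh.assembly)
    for n in asm.nodes:
        n.position = np.asarray(center) + R @ (n.position - device_center)
        n.rotation = rv.copy()
    return asm


def resample_deployed_cloud(
    mesh: "StentMesh", positions: np.ndarray, spacing: float
) -> np.ndarray:
    """Sample points along deployed struts at <= ``spacing`` apart."""
    pts = []
    for e in mesh.assembly.elements:
        a, b = positions[e.nodes[0]], positions[e.nodes[1]]
        m = max(1, int(math.ceil(np.linalg.norm(b - a) / spacing)))
        for t in np.linspace(0.0, 1.0, m + 1)[:-1]:
            pts.append(a + t * (b - a))
    return np.array(pts)


def stent_pose_transform(
    pts: np.ndarray,
    stent: StentSpec,
    B3D: np.ndarray,
    triad: np.ndarray,
    phi: float = 0.0,
    barycenter_device: np.ndarray | None = None,
) -> np.ndarray:
    """Rigidly carry device-coordinate points of one stent to a world pose.

    The stent's device-frame barycenter maps to ``B3D``; ``triad`` columns
    are the world axes of the stent frame and ``phi`` is the axial rotation
    applied first.
    """
    if barycenter_device is None:
        barycenter_device = np.array([0.0, 0.0, stent.axial_position])
    local = np.atleast_2d(pts) - barycenter_device
    cp, sp = math.cos(phi), math.sin(phi)
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return B3D + (local @ Rz.T) @ triad.T


# ----------------------------------------------------------------------
# YAML device files
# ----------------------------------------------------------------------


def graft_from_dict(d: dict) -> GraftSpec:
    stents = [
        StentSpec(
            n_peaks=int(s["n_peaks"]),
            height=float(s["height"]),
            diameter_proximal=float(s["diameter_proximal"]),
            diameter_distal=float(s["diameter_distal"]),
            wire_diameter=float(s.get("wire_diameter", 0.125)),
            axial_position=float(s["axial_position"]),
        )
        for s in d["stents"]
    ]
    fens = [
        Fenestration(
            stent_index=int(f["stent"]),
            angle=math.radians(float(f["angle_deg"])),
            axial_offset=float(f.get("axial_offset", 0.0)),
            radius=float(f["radius"]),
        )
        for f in d.get("fenestrations", [])
    ]
    markers = d.get("markers", "auto")
    if markers == "auto":
        mk = auto_markers(stents, fens)
    else:
        mk = [(int(m["stent"]), np.asarray(m["point"], float)) for m in markers or []]
    return GraftSpec(
        stents=stents,
        inter_stent_gap=float(d.get("inter_stent_gap", 2.0)),
        fenestrations=fens,
        markers=mk,
        launcher_diameter=float(d.get("launcher_diameter", 6.0)),
        name=str(d.get("name", "device")),
    )


def load_graft(path_or_name) -> GraftSpec:
    """Load a device YAML file, or a bundled fixture by bare name."""
    try:
        with open(path_or_name) as fh:
            return graft_from_dict(yaml.safe_load(fh))
    except (FileNotFoundError, IsADirectoryError):
        ref = resources.files("fmvsd.data") / "devices" / f"{path_or_name}.yaml"
        return graft_from_dict(yaml.safe_load(ref.read_text()))


def graft_to_dict(g: GraftSpec) -> dict:
    return {
        "name": g.name,
        "launcher_diameter": g.launcher_diameter,
        "inter_stent_gap": g.inter_stent_gap,
        "stents": [
            {
                "n_peaks": s.n_peaks,
                "height": s.height,
                "diameter_proximal": s.diameter_proximal,
                "diameter_distal": s.diameter_distal,
                "wire_diameter": s.wire_diameter,
                "axial_position": s.axial_position,
            }
            for s in g.stents
        ],
        "fenestrations": [
            {
                "stent": f.stent_index,
                "angle_deg": math.degrees(f.angle),
                "axial_offset": f.axial_offset,
                "radius": f.radius,
            }
            for f in g.fenestrations
        ],
        "markers": [
            {"stent": i, "point": np.asarray(p, float).tolist()} for i, p in g.markers
        ],
    }


def save_graft(g: GraftSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(graft_to_dict(g), fh, sort_keys=False)
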