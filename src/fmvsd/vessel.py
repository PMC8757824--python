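"""Vessel geometry, wall distance queries and deployment boxes.

Sign convention (used by the contact model throughout): signed distance is
*positive outside* the permitted volume and negative inside, so a stent
node's penetration of the wall is simply its positive signed distance.

The Stage-2 deployment box is the Boolean intersection of the target
stent's back-projection polyhedron with the vessel volume. Without an exact
mesh-Boolean kernel the intersection is computed on a voxel signed-distance
grid (max of the two fields) and re-meshed by marching cubes at 0.5 mm; the
same grid then serves as the rigid contact environment, with an exact fast
path when the polyhedron lies entirely inside the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import RegularGridInterpolator

from ._meshgeom import MeshDistance, mesh_contains
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes


class EmptyIntersectionError(RuntimeError):
    """The back-projection polyhedron does not meet the vessel volume."""


class NotWatertightError(ValueError):
    pass


# ----------------------------------------------------------------------
# Signed-distance sources
# ----------------------------------------------------------------------


class MeshSDF:
    """Signed distance to a watertight triangular mesh (positive outside)."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self._dist = MeshDistance(mesh.triangles)

    def signed_outside(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points)
        dist, closest = self._dist.query(pts)
        inside = mesh_contains(self.mesh, pts)
        sd = np.where(inside, -dist, dist)
        delta = pts - closest
        norm = np.linalg.norm(delta, axis=1)
        normal = np.zeros_like(delta)
        ok = norm > 1e-12
        normal[ok] = delta[ok] / norm[ok, None]
        normal[inside] *= -1.0
        return sd, normal


class TubeSDF:
    """Analytic tube-of-revolution: distance to a centerline minus the local
    radius. Exact for straight tubes; a good approximation when the radius
    varies slowly along the centerline (documented in the methods note)."""

    def __init__(self, centerline: np.ndarray, radii: np.ndarray, oversample: int = 4):
        c = np.asarray(centerline, float)
        r = np.broadcast_to(np.asarray(radii, float), (len(c),))
        # densify so nearest-sample lookup is smooth
        segs = np.linalg.norm(np.diff(c, axis=0), axis=1)
        pts, rr = [c[0]], [r[0]]
        for k, L in enumerate(segs):
            n = max(1, int(np.ceil(L * oversample)))
            for t in np.linspace(0, 1, n + 1)[1:]:
                pts.append(c[k] + t * (c[k + 1] - c[k]))
                rr.append(r[k] + t * (r[k + 1] - r[k]))
        self.points = np.array(pts)
        self.radii = np.array(rr)
        self._tree = cKDTree(self.points)

    def signed_outside(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points)
        d, idx = self._tree.query(pts)
        delta = pts - self.points[idx]
        norm = np.linalg.norm(delta, axis=1)
        normal = np.zeros_like(delta)
        ok = norm > 1e-12
        normal[ok] = delta[ok] / norm[ok, None]
        return norm - self.radii[idx], normal


class ConvexSDF:
    """Implicit function of a convex polyhedron: max of face-plane distances
    (exact Euclidean distance near faces, conservative at edges)."""

    def __init__(self, mesh: trimesh.Trimesh):
        # deduplicate face planes for speed
        n = mesh.face_normals
        o = np.einsum("ij,ij->i", n, mesh.triangles[:, 0])
        planes = np.unique(np.round(np.column_stack([n, o]), 9), axis=0)
        self.normals = planes[:, :3]
        self.offsets = planes[:, 3]

    def signed_outside(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points)
        d = pts @ self.normals.T - self.offsets
        k = np.argmax(d, axis=1)
        return d[np.arange(len(pts)), k], self.normals[k]


class GridSDF:
    """Trilinear interpolation of a signed-distance field on a regular grid;
    gradients (contact normals) by central differences."""

    def __init__(self, xs, ys, zs, values):
        self.xs, self.ys, self.zs = xs, ys, zs
        self.values = values
        self._f = RegularGridInterpolator(
            (xs, ys, zs), values, bounds_error=False, fill_value=None
        )
        gx, gy, gz = np.gradient(values, xs, ys, zs)
        self._g = [
            RegularGridInterpolator((xs, ys, zs), g, bounds_error=False, fill_value=None)
            for g in (gx, gy, gz)
        ]

    @classmethod
    def from_source(cls, source, bounds, spacing: float = 0.5, pad: float = 2.0):
        lo = np.asarray(bounds[0], float) - pad
        hi = np.asarray(bounds[1], float) + pad
        axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        sd, _ = source.signed_outside(pts)
        return cls(axes[0], axes[1], axes[2], sd.reshape(X.shape))

    def signed_outside(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points)
        sd = self._f(pts)
        g = np.column_stack([gi(pts) for gi in self._g])
        norm = np.linalg.norm(g, axis=1)
        ok = norm > 1e-12
        g[ok] = g[ok] / norm[ok, None]
        return sd, g


class MaxSDF:
    """Pointwise maximum of signed-distance sources = Boolean intersection."""

    def __init__(self, *sources):
        self.sources = sources

    def signed_outside(self, points):
        sds, normals = zip(*(s.signed_outside(points) for s in self.sources))
        sds = np.stack(sds)
        normals = np.stack(normals)
        k = np.argmax(sds, axis=0)
        idx = np.arange(sds.shape[1])
        return sds[k, idx], normals[k, idx]


# ----------------------------------------------------------------------
# Vessel container
# ----------------------------------------------------------------------


@dataclass
class VesselMesh:
    """Watertight vessel surface plus its centerline polyline and radii.

    ``analytic_sdf`` (optional) is an exact/near-exact signed-distance
    source attached by the synthetic generator; generic meshes fall back to
    triangle proximity queries.
    """

    mesh: trimesh.Trimesh
    centerline: np.ndarray
    radii: np.ndarray
    analytic_sdf: object | None = None

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, float).reshape(-1, 3)
        self.radii = np.broadcast_to(
            np.asarray(self.radii, float), (len(self.centerline),)
        ).copy()

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def sdf(self):
        if self.analytic_sdf is not None:
            return self.analytic_sdf
        if len(self.centerline) >= 2:
            # inscribed-tube approximation from the centerline radii; cached
            self.analytic_sdf = TubeSDF(self.centerline, self.radii)
            return self.analytic_sdf
        return MeshSDF(self.mesh)

    def signed_outside(self, points):
        return self.sdf().signed_outside(points)

    def save(self, path) -> None:
        self.mesh.export(path)

    @classmethod
    def from_file(cls, path, centerline=None, radii=None) -> "VesselMesh":
        mesh = trimesh.load_mesh(path)
        if centerline is None:
            centerline = np.zeros((0, 3))
            radii = np.zeros(0)
        return cls(mesh=mesh, centerline=centerline, radii=radii)


def closest_point_query(mesh: trimesh.Trimesh, points: np.ndarray):
    """Signed distance (negative inside), closest surface point and outward
    normal for each query point; exact nearest triangle."""
    pts = np.atleast_2d(points)
    dist, closest = MeshDistance(mesh.triangles).query(pts)
    inside = mesh_contains(mesh, pts) if mesh.is_watertight else np.zeros(len(pts), bool)
    sd = np.where(inside, -dist, dist)
    delta = pts - closest
    norm = np.linalg.norm(delta, axis=1)
    normal = np.where(inside[:, None], -delta, delta)
    ok = norm > 1e-12
    normal[ok] = normal[ok] / np.linalg.norm(normal[ok], axis=1)[:, None]
    return sd, closest, normal


# ----------------------------------------------------------------------
# Deployment box
# ----------------------------------------------------------------------


@dataclass
class DeploymentBox:
    """Rigid contact volume for one stent's individual deployment."""

    mesh: trimesh.Trimesh
    sdf: object
    provenance: dict = field(default_factory=dict)

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    def signed_outside(self, points):
        return self.sdf.signed_outside(points)


def build_deployment_box(
    vessel: VesselMesh,
    polyhedron: trimesh.Trimesh,
    resolution: float = 0.5,
    provenance: dict | None = None,
) -> DeploymentBox:
    """Boolean intersection of the back-projection polyhedron with the
    vessel volume (see module docstring for the voxel re-meshing scheme)."""
    if not polyhedron.is_watertight or not vessel.is_watertight:
        raise NotWatertightError("both volumes must be watertight")
    vsdf = vessel.sdf()
    psdf = ConvexSDF(polyhedron)

    sd_verts, _ = vsdf.signed_outside(polyhedron.vertices)
    if np.all(sd_verts < -1e-9):
        # polyhedron fully inside the vessel: intersection is the polyhedron
        lo, hi = polyhedron.bounds
        grid = GridSDF.from_source(psdf, (lo, hi), spacing=resolution)
        return DeploymentBox(
            mesh=polyhedron.copy(), sdf=grid, provenance=provenance or {}
        )

    lo = np.maximum(polyhedron.bounds[0], vessel.mesh.bounds[0])
    hi = np.minimum(polyhedron.bounds[1], vessel.mesh.bounds[1])
    if np.any(hi <= lo):
        raise EmptyIntersectionError("volumes do not overlap")
    inter = MaxSDF(vsdf, psdf)
    grid = GridSDF.from_source(inter, (lo, hi), spacing=resolution)
    if grid.values.min() >= 0.0:
        raise EmptyIntersectionError("voxel intersection is empty")
    verts, faces, _, _ = marching_cubes(
        grid.values, level=0.0, spacing=(resolution,) * 3
    )
    verts = verts + np.array([grid.xs[0], grid.ys[0], grid.zs[0]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    return DeploymentBox(mesh=mesh, sdf=grid, provenance=provenance or {})
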