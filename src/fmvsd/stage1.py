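"""Stage 1: global deployment approximation from a single view.

Step 1 positions the centerline-reduced graft model in the vessel: each
beam's midpoint is tethered by a penalty spring to the back-projection ray
of its stent's observed 2D barycenter, wall contact keeps the chain inside
the artery (with a radial offset equal to the stent radius, which centers
the device wherever the vessel is narrower than the stent), and the
assembly is relaxed to equilibrium. Depth along the viewing axis — the
single-view ambiguity — is initialized at the point of each barycenter ray
closest to the vessel centerline.

Step 2 reconstructs each stent geometrically about its new barycenter,
scaling the rest point cloud radially by the ratio of measured to nominal
deployment diameters (interpolated linearly proximal -> distal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .devices import GraftSpec, StentMesh
from .fem import (
    BeamAssembly,
    ContactEnvironment,
    PointConstraint,
    RayLocus,
    SolverParams,
    solve_equilibrium,
)
from .imaging import ProjectionModel, TargetObservation
from .vessel import VesselMesh

RAY_SPRING_STIFFNESS = 10.0  # N/mm
WALL_STIFFNESS = 100.0
WALL_DAMPING = 0.1


class AnnularConfinement:
    """Smooth wall constraint for the centerline chain.

    A node carrying a stent of radius r_s may move within
    ``max(r_vessel - r_s, 0)`` of the vessel centerline; beyond that the
    (linear) penalty pushes it back radially. Where the vessel is narrower
    than the stent the clearance collapses to zero and the field reduces to
    a smooth centering spring — the wall compresses the stent
    symmetrically, so its centerline rides the vessel centerline.
    """

    def __init__(self, centerline: np.ndarray, vessel_radii: np.ndarray, node_radii: np.ndarray):
        from scipy.spatial import cKDTree

        self.points = np.asarray(centerline, float)
        self.radii = np.asarray(vessel_radii, float)
        self.node_radii = np.asarray(node_radii, float)
        self._tree = cKDTree(self.points)

    def signed_outside(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        _, idx = self._tree.query(pts)
        delta = pts - self.points[idx]
        rho = np.linalg.norm(delta, axis=1)
        normal = np.divide(
            delta, rho[:, None], out=np.zeros_like(delta), where=rho[:, None] > 1e-12
        )
        clearance = np.maximum(self.radii[idx] - self.node_radii, 0.0)
        return rho - clearance, normal


@dataclass
class Stage1Result:
    barycenters: np.ndarray  # (n_stents, 3)
    triads: list[np.ndarray]
    converged: bool
    residual_px: np.ndarray  # |project(B3D) - observed barycenter| per stent
    report: dict = field(default_factory=dict)


def _minimal_rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation vector of the minimal rotation mapping +z to ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    v = np.cross(z, a)
    s = np.linalg.norm(v)
    c = float(z @ a)
    if s < 1e-12:
        return np.zeros(3) if c > 0 else np.array([np.pi, 0.0, 0.0])
    return v / s * np.arctan2(s, c)


def _ray_near_polyline(origin, direction, polyline) -> np.ndarray:
    """Point on the ray closest to a dense polyline (depth prior)."""
    t = (polyline - origin) @ direction
    t = np.maximum(t, 0.0)
    foot = origin + t[:, None] * direction
    k = int(np.argmin(np.linalg.norm(foot - polyline, axis=1)))
    return foot[k]


def position_centerline(
    assembly: BeamAssembly,
    observations: list[TargetObservation],
    projection: ProjectionModel,
    vessel: VesselMesh,
    graft: GraftSpec,
    params: SolverParams | None = None,
) -> Stage1Result:
    """Relax the reduced model under ray constraints and wall contact."""
    n = len(assembly.elements)
    if n != len(observations):
        raise ValueError(f"{n} beams but {len(observations)} observations")
    params = params or SolverParams(tol_force=1e-3, tol_ke=1e-9, max_steps=30000)

    rays = []
    for obs in observations:
        o, d = projection.ray(obs.barycenter2d)
        rays.append(RayLocus(o, d))

    # densify the centerline (depth prior + confinement field)
    cl = vessel.centerline
    have_radii = len(vessel.radii) == len(cl) and len(cl) > 0
    dense, dense_r = [], []
    for k, (a, b) in enumerate(zip(cl[:-1], cl[1:])):
        m = max(1, int(np.ceil(np.linalg.norm(b - a))))
        for t in np.linspace(0, 1, m, endpoint=False):
            dense.append(a + t * (b - a))
            if have_radii:
                dense_r.append(vessel.radii[k] + t * (vessel.radii[k + 1] - vessel.radii[k]))
    dense.append(cl[-1])
    if have_radii:
        dense_r.append(vessel.radii[-1])
    dense = np.array(dense)
    if not have_radii:
        sd, _ = vessel.signed_outside(dense)
        dense_r = -sd  # local inscribed radius from the wall distance field
    dense_r = np.asarray(dense_r)

    mids = np.array(
        [_ray_near_polyline(r.origin, r.direction, dense) for r in rays]
    )
    tangents = np.zeros((n, 3))
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        t = mids[hi] - mids[lo]
        nt = np.linalg.norm(t)
        tangents[i] = t / nt if nt > 1e-9 else np.array([0.0, 0.0, 1.0])

    for i, e in enumerate(assembly.elements):
        half = 0.5 * e.l0 * tangents[i]
        rv = _minimal_rotation_to(tangents[i])
        na, nb = e.nodes
        assembly.nodes[na].position = mids[i] - half
        assembly.nodes[nb].position = mids[i] + half
        assembly.nodes[na].rotation = rv.copy()
        assembly.nodes[nb].rotation = rv.copy()

    assembly.point_constraints = [
        PointConstraint(assembly.elements[i].nodes, rays[i], RAY_SPRING_STIFFNESS)
        for i in range(n)
    ]

    # smooth wall confinement with per-node radial offset = stent radius
    node_radii = np.zeros(assembly.n_nodes)
    for i, s in enumerate(graft.stents):
        r = 0.25 * (s.diameter_proximal + s.diameter_distal)
        na, nb = assembly.elements[i].nodes
        node_radii[na] = max(node_radii[na], r)
        node_radii[nb] = max(node_radii[nb], r)
    confinement = AnnularConfinement(dense, dense_r, node_radii)
    env = ContactEnvironment(
        confinement, stiffness=WALL_STIFFNESS, damping=WALL_DAMPING, offset=0.0
    )

    res = solve_equilibrium(assembly, contact_env=env, params=params)
    assembly.set_state(res.positions, res.quats)

    pos = res.positions
    barys = np.array(
        [0.5 * (pos[e.nodes[0]] + pos[e.nodes[1]]) for e in assembly.elements]
    )
    # element tangents from converged nodes; transverse axes by parallel
    # transport along the chain
    triads = []
    u = np.array([1.0, 0.0, 0.0])
    for i, e in enumerate(assembly.elements):
        t = pos[e.nodes[1]] - pos[e.nodes[0]]
        t = t / np.linalg.norm(t)
        u = u - (u @ t) * t
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-9 else np.array([0.0, 1.0, 0.0])
        triads.append(np.column_stack([u, np.cross(t, u), t]))

    proj_b, _ = projection.project(barys)
    resid = np.array(
        [
            np.linalg.norm(proj_b[i] - observations[i].barycenter2d)
            for i in range(n)
        ]
    )
    return Stage1Result(
        barycenters=barys,
        triads=triads,
        converged=res.converged,
        residual_px=resid,
        report={"steps": res.steps, "residual_force": res.residual},
    )


def reconstruct_stent(
    mesh: StentMesh,
    B3D: np.ndarray,
    triad: np.ndarray,
    apparent_diam_proximal: float,
    apparent_diam_distal: float,
) -> np.ndarray:
    """Geometric reconstruction of one stent about its new barycenter.

    Every rest-cloud vector V is scaled radially by the ratio of the
    measured to the nominal deployment diameter, both interpolated linearly
    from the proximal to the distal end; the axial component is preserved.
    Diameters here are in mm (image measurements are converted by the local
    magnification upstream).
    """
    if apparent_diam_proximal <= 0 or apparent_diam_distal <= 0:
        raise ValueError("measured diameters must be positive")
    V = mesh.V
    z = V[:, 2]
    zmin, zmax = z.min(), z.max()
    u = (z - zmin) / max(zmax - zmin, 1e-12)
    d_meas = apparent_diam_proximal + u * (apparent_diam_distal - apparent_diam_proximal)
    s = mesh.spec
    d_nom = s.diameter_proximal + u * (s.diameter_distal - s.diameter_proximal)
    scale = d_meas / d_nom
    Vd = V.copy()
    Vd[:, 0] *= scale
    Vd[:, 1] *= scale
    return np.asarray(B3D) + Vd @ np.asarray(triad).T
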