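"""Stage 2: per-stent refinement against the single-view target.

Step 1 recovers each stent's rotation about its own axis by minimizing,
with differential evolution, the mean distance between the projected
reconstructed stent and its nearest neighbour in the target pixel set.
Plain Z-stents are axisymmetric with period theta = 2*pi/n_peaks, so only
Phi mod theta is observable; stents carrying radiopaque markers use the
marker-only distance d_RM, which pins the rotation uniquely.

Step 2 deploys each stent's full strut model individually: the posed
nominal ring is crimped radially to the launcher diameter by a ramped
penalty, released, and relaxed against its rigid deployment box through
penalty contact (time step reduced after first contact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, linear_sum_assignment, minimize_scalar
from scipy.spatial import cKDTree

from .devices import StentMesh, pose_assembly, resample_deployed_cloud
from .fem import (
    ContactEnvironment,
    EquilibriumResult,
    RadialConstraint,
    SolverParams,
    solve_equilibrium,
)
from .imaging import ProjectionModel, TargetObservation
from .vessel import DeploymentBox


@dataclass
class RotationResult:
    """Recovered axial rotation of one stent."""

    phi: float  # rad, in [0, theta) for axisymmetric mode, [0, 2pi) for markers
    residual: float  # px: d (cloud) or d_RM (markers)
    mode: str  # "axisymmetric" | "marker"
    theta: float  # periodic angle 2pi/n_peaks (axisymmetric), else 2pi

    def __post_init__(self):
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def _rotated_world(cloud_local, B3D, triad, phi):
    cp, sp = math.cos(phi), math.sin(phi)
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return np.asarray(B3D) + (cloud_local @ Rz.T) @ np.asarray(triad).T


def cloud_image_distance(
    cloud_local: np.ndarray,
    B3D: np.ndarray,
    triad: np.ndarray,
    phi: float,
    projection: ProjectionModel,
    target_tree: cKDTree,
) -> float:
    """d(Phi): mean nearest-neighbour pixel distance, projected cloud ->
    target pixel set."""
    world = _rotated_world(cloud_local, B3D, triad, phi)
    xy, ok = projection.project(world)
    d, _ = target_tree.query(xy[ok])
    return float(np.mean(d))


def marker_image_distance(
    markers_local: np.ndarray,
    B3D: np.ndarray,
    triad: np.ndarray,
    phi: float,
    projection: ProjectionModel,
    marker_px: np.ndarray,
) -> float:
    """d_RM(Phi): mean distance over the minimum-cost pairing of projected
    spec markers with detected marker dots."""
    world = _rotated_world(markers_local, B3D, triad, phi)
    xy, _ = projection.project(world)
    cost = np.linalg.norm(xy[:, None, :] - marker_px[None, :, :], axis=2)
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].mean())


def recover_rotation(
    cloud_local: np.ndarray,
    B3D: np.ndarray,
    triad: np.ndarray,
    observation: TargetObservation,
    projection: ProjectionModel,
    n_peaks: int | None = None,
    markers_local: np.ndarray | None = None,
    seed: int = 0,
    subsample: int = 400,
) -> RotationResult:
    """Minimize d(Phi) (or d_RM with markers) by differential evolution.

    ``cloud_local`` (and ``markers_local``) are expressed about the stent's
    own axis, i.e. relative to its barycenter in the stent frame, so that
    rotation by Phi is well defined.
    """
    if markers_local is not None:
        marker_px = np.asarray(observation.marker_points2d, float).reshape(-1, 2)
        if len(marker_px) < 2 or len(markers_local) < 2:
            raise ValueError("marker mode needs at least 2 markers")
        theta = 2.0 * math.pi

        def cost(phi):
            return marker_image_distance(
                markers_local, B3D, triad, float(phi), projection, marker_px
            )

        mode = "marker"
    else:
        if len(observation.pixel_set) == 0:
            raise ValueError("empty target pixel set")
        theta = 2.0 * math.pi / n_peaks if n_peaks else 2.0 * math.pi
        tree = cKDTree(np.asarray(observation.pixel_set, float))
        cl = np.asarray(cloud_local, float)
        if len(cl) > subsample:
            cl = cl[:: max(1, len(cl) // subsample)]

        def cost(phi):
            return cloud_image_distance(cl, B3D, triad, float(phi), projection, tree)

        mode = "axisymmetric"

    res = differential_evolution(
        lambda x: cost(x[0]),
        bounds=[(0.0, theta)],
        popsize=20,
        tol=1e-3,
        seed=seed,
        polish=False,
        maxiter=60,
    )
    # d(Phi) has narrow minima and a deceptive half-period mirror basin for
    # zig-zag rings; a deterministic coarse scan guards the global basin
    grid_step = math.radians(0.5)
    grid = np.arange(0.0, theta, grid_step)
    grid_vals = [cost(g) for g in grid]
    candidates = [(float(res.fun), float(res.x[0])),
                  (float(np.min(grid_vals)), float(grid[int(np.argmin(grid_vals))]))]
    _, phi0 = min(candidates)
    # golden-section polish in a bracket around the best candidate
    half = max(grid_step, theta / 40.0)
    pol = minimize_scalar(
        cost, bounds=(phi0 - half, phi0 + half), method="bounded",
        options={"xatol": 1e-5},
    )
    phi = float(pol.x) % theta
    return RotationResult(phi=phi, residual=float(pol.fun), mode=mode, theta=theta)


@dataclass
class DeploymentResult:
    positions: np.ndarray
    cloud: np.ndarray
    equilibrium: EquilibriumResult
    report: dict = field(default_factory=dict)


def deploy_stent(
    mesh: StentMesh,
    phi: float,
    B3D: np.ndarray,
    triad: np.ndarray,
    launcher_diameter: float,
    box: DeploymentBox,
    params: SolverParams | None = None,
    crimp_increments: int = 5,
    cloud_spacing: float | None = None,
) -> DeploymentResult:
    """Crimp, release and relax one stent inside its rigid deployment box.

    The strut lattice (316L wire, Euler-Bernoulli corotational beams) is
    posed at (B3D, triad, Phi), crimped to the launcher radius by a ramped
    radial penalty, then released against box contact until equilibrium.
    """
    spec = mesh.spec
    if launcher_diameter >= min(spec.diameter_proximal, spec.diameter_distal):
        raise ValueError("launcher must be narrower than the stent")
    sd0, _ = box.signed_outside(np.atleast_2d(B3D))
    if sd0[0] > 0.5 * max(spec.diameter_proximal, spec.diameter_distal):
        raise ValueError("stent placed entirely outside its deployment box")

    asm = pose_assembly(mesh, B3D, triad, phi)
    axis = np.asarray(triad)[:, 2]
    nominal_r = np.array([spec.radius_at(z) for z in mesh.node_z_local])
    target_r = launcher_diameter / 2.0
    rc = RadialConstraint(
        np.arange(asm.n_nodes), B3D, axis, nominal_r, stiffness=5.0
    )
    asm.point_constraints.append(rc)
    crimp_params = SolverParams(
        axial_scale=1e-3, tol_force=5e-3, tol_ke=1e-7, max_steps=4000, mass_margin=2.0
    )
    for f in np.linspace(1.0, 0.0, crimp_increments + 1)[1:]:
        rc.target_radii[:] = target_r + f * (nominal_r - target_r)
        res = solve_equilibrium(asm, params=crimp_params)
        asm.set_state(res.positions, res.quats)
    crimp_energy = res.elastic_energy

    # release under box contact
    asm.point_constraints.clear()
    params = params or SolverParams(
        axial_scale=1e-3, tol_force=1e-3, tol_ke=1e-7, max_steps=30000, mass_margin=2.0
    )
    env = ContactEnvironment(
        box.sdf, stiffness=5.0, damping=0.05, offset=spec.wire_diameter / 2.0
    )
    res = solve_equilibrium(asm, contact_env=env, params=params)
    spacing = cloud_spacing or 0.4
    cloud = resample_deployed_cloud(mesh, res.positions, spacing)
    return DeploymentResult(
        positions=res.positions,
        cloud=cloud,
        equilibrium=res,
        report={
            "steps": res.steps,
            "converged": res.converged,
            "crimp_energy": crimp_energy,
            "released_energy": res.elastic_energy,
        },
    )
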