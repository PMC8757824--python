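"""Stage 2: rotation recovery and individual deployment."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fmvsd.devices import StentSpec, build_zstent_mesh
from fmvsd.imaging import ProjectionModel, make_observation
from fmvsd.stage2 import (
    RotationResult,
    cloud_image_distance,
    deploy_stent,
    recover_rotation,
)
from fmvsd.vessel import DeploymentBox, GridSDF


def render_pixels(projection, world_pts):
    xy, ok = projection.project(world_pts)
    return np.unique(np.round(xy[ok]).astype(int), axis=0).astype(float)


@pytest.fixture(scope="module")
def ring_setup():
    spec = StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)
    mesh = build_zstent_mesh(spec, (1.5, 0.3))
    projection = ProjectionModel.c_arm()
    B = np.array([0.0, 0.0, 0.0])
    triad = np.eye(3)
    return spec, mesh, projection, B, triad


def observation_at(mesh, projection, B, triad, phi_true, markers_local=None):
    c, s = math.cos(phi_true), math.sin(phi_true)
    Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    world = B + (mesh.V @ Rz.T) @ triad.T
    px = render_pixels(projection, world)
    marker_px = None
    if markers_local is not None:
        mw = B + (markers_local @ Rz.T) @ triad.T
        marker_px, _ = projection.project(mw)
    return make_observation(px, [0.0, 1.0], marker_points2d=marker_px)


class TestRotationRecovery:
    def test_self_match_at_zero(self, ring_setup):
        spec, mesh, P, B, triad = ring_setup
        obs = observation_at(mesh, P, B, triad, 0.0)
        rot = recover_rotation(mesh.V, B, triad, obs, P, n_peaks=spec.n_peaks, seed=3)
        err = min(rot.phi, rot.theta - rot.phi)
        assert math.degrees(err) < 1.0

    def test_axisymmetric_mod_theta(self, ring_setup):
        """Phi_true = 100 deg with 5 peaks (theta = 72): recovered
        Phi = 28 deg (mod 72) within 2 deg, and the optimizer argmin agrees
        with a 0.1-degree brute-force grid search."""
        spec, mesh, P, B, triad = ring_setup
        phi_true = math.radians(100.0)
        obs = observation_at(mesh, P, B, triad, phi_true)
        rot = recover_rotation(mesh.V, B, triad, obs, P, n_peaks=spec.n_peaks, seed=5)
        assert rot.mode == "axisymmetric"
        assert rot.theta == pytest.approx(2 * math.pi / 5)
        expect = phi_true % rot.theta  # 28 degrees
        err = abs(rot.phi - expect)
        err = min(err, rot.theta - err)
        assert math.degrees(err) < 2.0

        # independent oracle: dense grid search over d(Phi)
        tree = cKDTree(obs.pixel_set)
        cl = mesh.V[:: max(1, len(mesh.V) // 400)]
        grid = np.radians(np.arange(0.0, 72.0, 0.1))
        vals = [cloud_image_distance(cl, B, triad, g, P, tree) for g in grid]
        phi_grid = grid[int(np.argmin(vals))]
        gerr = abs(rot.phi - phi_grid)
        gerr = min(gerr, rot.theta - gerr)
        assert math.degrees(gerr) < 2.0

    def test_marker_mode_unique_rotation(self, ring_setup):
        """3 markers, Phi_true = 25 deg: recovered exactly (no mod-theta
        ambiguity) within 1 degree."""
        spec, mesh, P, B, triad = ring_setup
        rng = np.random.default_rng(0)
        ang = np.array([0.2, 1.9, 3.4])
        markers_local = np.column_stack(
            [14 * np.cos(ang), 14 * np.sin(ang), rng.uniform(-5, 5, 3)]
        )
        phi_true = math.radians(25.0)
        obs = observation_at(mesh, P, B, triad, phi_true, markers_local)
        rot = recover_rotation(
            mesh.V, B, triad, obs, P, n_peaks=spec.n_peaks,
            markers_local=markers_local, seed=11,
        )
        assert rot.mode == "marker"
        err = abs(rot.phi - phi_true)
        err = min(err, 2 * math.pi - err)
        assert math.degrees(err) < 1.0

    def test_periodicity_of_cost(self, ring_setup):
        """d(Phi) is theta-periodic for an axisymmetric stent."""
        spec, mesh, P, B, triad = ring_setup
        obs = observation_at(mesh, P, B, triad, 0.7)
        tree = cKDTree(obs.pixel_set)
        cl = mesh.V[:: max(1, len(mesh.V) // 300)]
        theta = 2 * math.pi / spec.n_peaks
        for g in np.linspace(0.0, theta, 7):
            a = cloud_image_distance(cl, B, triad, g, P, tree)
            b = cloud_image_distance(cl, B, triad, g + theta, P, tree)
            assert abs(a - b) < 1e-6

    def test_error_conditions(self, ring_setup):
        spec, mesh, P, B, triad = ring_setup
        obs = observation_at(mesh, P, B, triad, 0.0)
        obs.pixel_set = np.zeros((0, 2))
        with pytest.raises(ValueError):
            recover_rotation(mesh.V, B, triad, obs, P, n_peaks=5, seed=0)
        obs2 = observation_at(mesh, P, B, triad, 0.0)
        obs2.marker_points2d = np.array([[10.0, 10.0]])
        with pytest.raises(ValueError):
            recover_rotation(
                mesh.V, B, triad, obs2, P, n_peaks=5,
                markers_local=np.array([[14.0, 0.0, 0.0]]), seed=0,
            )


def cylinder_box(radius, half_height=12.0, spacing=0.5):
    class CylSDF:
        def signed_outside(self, pts):
            pts = np.atleast_2d(pts)
            rho = np.linalg.norm(pts[:, :2], axis=1)
            normal = np.zeros_like(pts)
            ok = rho > 1e-12
            normal[ok, :2] = pts[ok, :2] / rho[ok, None]
            return rho - radius, normal

    import trimesh

    mesh = trimesh.creation.cylinder(radius=radius, height=2 * half_height, sections=64)
    return DeploymentBox(mesh=mesh, sdf=CylSDF())


@pytest.fixture(scope="module")
def stent():
    spec = StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)
    return build_zstent_mesh(spec, (1.5, 0.4))


class TestDeployment:

    def test_free_recovery_in_generous_box(self, stent):
        """Box wider than nominal + 2 mm: deployed diameter within 2% of
        nominal (pure elastic recovery)."""
        box = cylinder_box(16.0)
        dep = deploy_stent(stent, 0.3, np.zeros(3), np.eye(3), 6.0, box)
        radii = np.linalg.norm(dep.positions[:, :2], axis=1)
        assert radii.max() == pytest.approx(14.0, rel=0.02)
        assert radii.min() == pytest.approx(14.0, rel=0.02)

    def test_confined_by_undersized_cylinder(self, stent):
        """Rigid cylinder at 80% nominal: all nodes inside within 0.05 mm
        penetration."""
        box = cylinder_box(0.4 * 28.0)
        dep = deploy_stent(stent, 0.0, np.zeros(3), np.eye(3), 6.0, box)
        radii = np.linalg.norm(dep.positions[:, :2], axis=1)
        assert radii.max() <= 0.4 * 28.0 + 0.05

    def test_crimped_state_respects_launcher(self, stent):
        """During the crimp phase every node radius reaches the launcher
        radius (+ wire radius tolerance) before release."""
        from fmvsd.devices import pose_assembly
        from fmvsd.fem import SolverParams, solve_equilibrium
        from fmvsd.fem.constraints import RadialConstraint

        asm = pose_assembly(stent, np.zeros(3), np.eye(3), 0.0)
        nominal_r = np.array([stent.spec.radius_at(z) for z in stent.node_z_local])
        rc = RadialConstraint(np.arange(asm.n_nodes), np.zeros(3), [0, 0, 1],
                              nominal_r, stiffness=5.0)
        asm.point_constraints.append(rc)
        p = SolverParams(axial_scale=1e-3, tol_force=5e-3, max_steps=4000, mass_margin=2.0)
        for f in np.linspace(1.0, 0.0, 6)[1:]:
            rc.target_radii[:] = 3.0 + f * (nominal_r - 3.0)
            res = solve_equilibrium(asm, params=p)
            asm.set_state(res.positions, res.quats)
        radii = np.linalg.norm(res.positions[:, :2], axis=1)
        assert radii.max() <= 3.0 + stent.spec.wire_diameter / 2 + 0.15

    def test_release_never_adds_energy(self, stent):
        """Elastic energy at equilibrium <= energy of the crimped state."""
        box = cylinder_box(12.0)
        dep = deploy_stent(stent, 0.0, np.zeros(3), np.eye(3), 6.0, box)
        assert dep.equilibrium.converged
        assert dep.report["released_energy"] <= dep.report["crimp_energy"]

    def test_launcher_wider_than_stent_rejected(self, stent):
        box = cylinder_box(16.0)
        with pytest.raises(ValueError):
            deploy_stent(stent, 0.0, np.zeros(3), np.eye(3), 30.0, box)
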