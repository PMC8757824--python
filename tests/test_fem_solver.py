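"""Equilibrium solver: analytic deflections, contact law, energy behaviour."""

import numpy as np
import pytest

from conftest import make_cantilever, make_ring
from fmvsd.fem import (
    ContactEnvironment,
    PointConstraint,
    PointLocus,
    SolverParams,
    contact_force,
    elastic_energy,
    solve_equilibrium,
    solve_static_newton,
)
from fmvsd.fem.constraints import RadialConstraint


def timoshenko_tip_deflection(P, L, E, r, shear_factor=0.9, nu=0.3):
    I = np.pi * r**4 / 4
    A = np.pi * r**2
    G = E / (2 * (1 + nu))
    return P * L**3 / (3 * E * I) + P * L / (G * shear_factor * A)


class TestStatics:
    def test_rest_configuration_is_equilibrium(self, steel_section):
        a, _ = make_cantilever(5)
        res = solve_equilibrium(a, params=SolverParams(max_steps=10))
        assert res.converged
        assert res.residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.positions, a.positions())

    def test_cantilever_matches_timoshenko_closed_form(self):
        """20 elements, L=100 mm, r=0.5 mm, E=193 GPa, tip load 0.01 N."""
        a, _ = make_cantilever(20, length=100.0, radius=0.5, shear_factor=0.9)
        f = np.zeros((21, 3))
        f[-1, 1] = 0.01
        res = solve_equilibrium(
            a,
            params=SolverParams(axial_scale=1e-3, tol_force=1e-6, max_steps=60000),
            external_forces=f,
        )
        assert res.converged
        delta = timoshenko_tip_deflection(0.01, 100.0, 193000.0, 0.5)
        assert res.positions[-1, 1] == pytest.approx(delta, rel=0.01)

    def test_mesh_refinement_converges_monotonically(self):
        """Tip-moment cantilever bends into a circular arc; the corotational
        discretization error vs the arc closed form decreases as the
        element count doubles from 4 to 64."""
        L, r, E = 50.0, 2.0, 193000.0
        I = np.pi * r**4 / 4
        M = 0.8 * E * I / L  # total rotation 0.8 rad
        k = M / (E * I)
        x_exact = np.sin(k * L) / k
        y_exact = (1 - np.cos(k * L)) / k
        errs = []
        for n in (4, 8, 16, 32, 64):
            a, _ = make_cantilever(n, length=L, radius=r, shear_factor=None)
            tq = np.zeros((n + 1, 3))
            tq[-1, 2] = M
            res = solve_static_newton(a, external_torques=tq, tol_force=1e-6, n_load_steps=16)
            assert res.converged
            tip = res.positions[-1]
            errs.append(np.hypot(tip[0] - x_exact, tip[1] - y_exact))
        assert all(b < a for a, b in zip(errs, errs[1:])), errs

    def test_ring_recovers_nominal_diameter_after_crimp(self):
        """A crimped elastic ring released without obstacle returns to its
        rest diameter (the unique energy minimum) within 2%."""
        R = 14.0
        a, _ = make_ring(radius=R, n=72)
        rc = RadialConstraint(np.arange(a.n_nodes), [0, 0, 0], [0, 0, 1], R, stiffness=5.0)
        a.point_constraints.append(rc)
        loose = SolverParams(axial_scale=1e-3, tol_force=5e-3, max_steps=4000)
        for f in np.linspace(1.0, 3.0 / R, 6):
            rc.target_radii[:] = max(f * R, 3.0)
            res = solve_equilibrium(a, params=loose)
            a.set_state(res.positions, res.quats)
        crimped = np.linalg.norm(res.positions[:, :2], axis=1)
        assert crimped.max() < 3.2
        a.point_constraints.clear()
        res = solve_equilibrium(
            a, params=SolverParams(axial_scale=1e-3, tol_force=1e-5, max_steps=60000)
        )
        assert res.converged
        radii = np.linalg.norm(res.positions[:, :2], axis=1)
        assert radii.min() == pytest.approx(R, rel=0.02)
        assert radii.max() == pytest.approx(R, rel=0.02)

    def test_joint_transmits_force_but_no_moment(self, steel_section):
        """Two beams joined in translation only: a 90-degree kink relaxes to
        equilibrium without straightening (no moment across the joint)."""
        from fmvsd.fem import BeamAssembly

        a = BeamAssembly()
        a.add_node([0, 0, 0], fixed_dofs=np.ones(6, bool))
        a.add_node([10, 0, 0], fixed_dofs=np.ones(6, bool))
        a.add_node([10, 0, 0])
        a.add_node([10, 10, 0])
        a.add_element(0, 1, steel_section)
        a.add_element(2, 3, steel_section, rest_frame=np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]]).T)
        a.add_joint(1, 2)
        res = solve_equilibrium(a, params=SolverParams(tol_force=1e-6, max_steps=20000))
        assert res.converged
        # the kink persists: second beam still points along +y
        d = res.positions[3] - res.positions[2]
        assert d[1] == pytest.approx(10.0, abs=1e-6)
        assert abs(d[0]) < 1e-6


class TestContactLaw:
    def test_separated_gives_zero(self):
        assert contact_force(-0.1, 0.0, 100.0, 1.0) == 0.0

    def test_linear_spring(self):
        assert contact_force(0.05, 0.0, 100.0, 0.0) == pytest.approx(5.0)

    def test_non_adhesive_clamp(self):
        # separating fast enough that k*d + c*v < 0 -> clamped to 0
        d, v, k, c = 0.05, -10.0, 100.0, 1.0
        assert k * d + c * v < 0
        assert contact_force(d, v, k, c) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            contact_force(0.1, 0.0, -1.0, 0.0)

    def test_confined_ring_respects_rigid_cylinder(self):
        """Ring released inside a rigid cylinder 80% of nominal conforms to
        it with sub-0.05 mm penetration."""

        class CylinderSDF:
            def __init__(self, radius):
                self.radius = radius

            def signed_outside(self, pts):
                pts = np.atleast_2d(pts)
                rho = np.linalg.norm(pts[:, :2], axis=1)
                normal = np.zeros_like(pts)
                ok = rho > 1e-12
                normal[ok, :2] = pts[ok, :2] / rho[ok, None]
                return rho - self.radius, normal

        R = 14.0
        a, _ = make_ring(radius=R, n=72)
        env = ContactEnvironment(CylinderSDF(0.8 * R), stiffness=5.0, damping=0.05)
        res = solve_equilibrium(
            a,
            contact_env=env,
            params=SolverParams(axial_scale=1e-3, tol_force=1e-4, max_steps=60000),
        )
        assert res.converged
        radii = np.linalg.norm(res.positions[:, :2], axis=1)
        assert radii.max() <= 0.8 * R + 0.05
        assert res.report["contact_triggered"]
        assert res.report["dt_final"] < SolverParams().dt


class TestDynamics:
    def test_energy_drift_below_5_percent_undamped(self, steel_section):
        """Free vibration with zero damping: total energy drift < 5% over
        1000 explicit steps (integrator sanity)."""
        from fmvsd.fem import BeamAssembly
        from fmvsd.fem.corotational import internal_forces_compiled

        a, _ = make_cantilever(8, length=40.0, radius=1.0)
        # pluck the tip
        pos0 = a.positions()
        pos0[-1, 1] += 0.5
        for n, p in zip(a.nodes, pos0):
            n.position = p
        res = solve_equilibrium(
            a, params=SolverParams(damping=0.0, max_steps=1000, tol_force=0.0, tol_ke=0.0)
        )
        e_start = elastic_energy(a)
        e_end = res.elastic_energy + res.kinetic_energy
        assert abs(e_end - e_start) / e_start < 0.05

    def test_point_constraint_pulls_to_target(self, steel_section):
        from fmvsd.fem import BeamAssembly

        a = BeamAssembly()
        a.add_node([0, 0, 0], fixed_dofs=np.ones(6, bool))
        a.add_node([10, 0, 0])
        a.add_element(0, 1, steel_section)
        a.point_constraints.append(PointConstraint((1,), PointLocus(np.array([10.0, 0.2, 0.0])), 50.0))
        res = solve_equilibrium(a, params=SolverParams(tol_force=1e-6, max_steps=30000))
        assert res.converged
        assert 0.0 < res.positions[1, 1] < 0.2  # spring vs beam stiffness

    def test_determinism(self):
        a1, _ = make_ring(radius=10.0, n=36)
        a2, _ = make_ring(radius=10.0, n=36)
        for a in (a1, a2):
            a.nodes[0].position = a.nodes[0].position + np.array([0.0, 0.5, 0.0])
        p = SolverParams(axial_scale=1e-3, tol_force=1e-5, max_steps=20000)
        r1 = solve_equilibrium(a1, params=p)
        r2 = solve_equilibrium(a2, params=p)
        assert np.array_equal(r1.positions, r2.positions)
        assert r1.steps == r2.steps


def test_assembly_json_roundtrip(tmp_path, steel_section):
    """Serialized assemblies reload with identical geometry and sections."""
    from fmvsd.fem import load_assembly, save_assembly

    a, _ = make_cantilever(4, length=20.0)
    a.add_joint(1, 2)
    path = tmp_path / "assembly.json"
    save_assembly(a, path)
    b = load_assembly(path)
    assert np.array_equal(a.positions(), b.positions())
    assert a.joints == b.joints
    assert len(a.elements) == len(b.elements)
    for ea, eb in zip(a.elements, b.elements):
        assert ea.l0 == eb.l0
        assert ea.section == eb.section
        assert np.array_equal(ea.rest_frame, eb.rest_frame)
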