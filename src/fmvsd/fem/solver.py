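"""Damped dynamic-relaxation equilibrium solver with penalty contact.

Masses are fictitious: each translational/rotational DOF gets a lumped mass
proportional to dt^2 times the stiffness attached to it, so the explicit
central-difference sweep is unconditionally stable at the chosen step and
the convergence rate is governed only by the structure's stiffness contrast.
The default damping scheme is kinetic (velocities are zeroed whenever the
total kinetic energy peaks), which is robust for the strongly nonlinear
crimp/release paths of stent deployment; a viscous damping-ratio mode is
also available.

Contact follows the regularized spring-dashpot penalty model: each
penetrating node feels a normal force k*d + c*v, clamped non-adhesive. After
the first nonzero contact force the time step is reduced once by a fixed
factor (masses are rebuilt for the new step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._quat import normalize_quat, quat_mul, rotvec_to_quat
from .assembly import BeamAssembly
from .corotational import internal_forces_compiled


class SolverFailure(RuntimeError):
    def __init__(self, message, positions=None, quats=None):
        super().__init__(message)
        self.positions = positions
        self.quats = quats


def contact_force(
    penetration_depth: float, approach_speed: float, stiffness: float, damping: float
) -> float:
    """Scalar normal contact force (N) of the spring-dashpot penalty model.

    Zero when separated (penetration <= 0); otherwise k*d + c*v clamped to
    be non-adhesive (never negative).
    """
    if stiffness <= 0.0 or damping < 0.0:
        raise ValueError("stiffness must be > 0 and damping >= 0")
    if penetration_depth <= 0.0:
        return 0.0
    return max(0.0, stiffness * penetration_depth + damping * approach_speed)


class ContactEnvironment:
    """Rigid environment confining nodes; wraps a signed-distance source.

    ``sdf`` must provide ``signed_outside(points) -> (sd, normal)`` where
    sd > 0 means the point lies outside the allowed volume and ``normal`` is
    the unit direction of increasing sd. ``offset`` (mm) inflates the
    contact surface inward (e.g. by the strut wire radius).
    """

    def __init__(self, sdf, stiffness: float = 1e3, damping: float = 1.0, offset: float = 0.0):
        if stiffness <= 0 or damping < 0:
            raise ValueError("stiffness must be > 0 and damping >= 0")
        self.sdf = sdf
        self.stiffness = stiffness
        self.damping = damping
        self.offset = offset

    def penetration(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd, normal = self.sdf.signed_outside(points)
        return sd + self.offset, normal


@dataclass
class SolverParams:
    """Dynamic-relaxation settings (see module docstring)."""

    dt: float = 1.0
    max_steps: int = 60000
    tol_force: float = 1e-4  # N, max residual force on any free node
    tol_ke: float = 1e-8  # N*mm
    damping: str | float = "kinetic"  # "kinetic" or a viscous damping ratio
    mass_margin: float = 4.0
    axial_scale: float = 1.0
    dt_contact_factor: float = 0.1
    char_length: float | None = None  # torque residuals compared to tol*L
    diverge_limit: float = 1e6


@dataclass
class EquilibriumResult:
    positions: np.ndarray
    quats: np.ndarray
    converged: bool
    steps: int
    residual: float
    kinetic_energy: float
    elastic_energy: float
    report: dict = field(default_factory=dict)

    def rotvecs(self) -> np.ndarray:
        return Rotation.from_quat(self.quats).as_rotvec()


def _masses(comp, env, constraints, params, dt):
    kt, kr = comp.nodal_stiffness_estimates()
    for c in constraints:
        kt = kt + c.stiffness_at(comp.n_nodes)
    if env is not None:
        kt = kt + env.stiffness
    kt = np.maximum(kt, 1e-12)
    kr = np.maximum(kr, 1e-12)
    m = params.mass_margin * dt * dt * kt
    I = params.mass_margin * dt * dt * kr
    return m[:, None], I[:, None]


def solve_equilibrium(
    assembly: BeamAssembly,
    contact_env: ContactEnvironment | None = None,
    params: SolverParams | None = None,
    external_forces: np.ndarray | None = None,
    external_torques: np.ndarray | None = None,
) -> EquilibriumResult:
    """Relax an assembly to static equilibrium.

    Deterministic given identical inputs. Converged when the largest nodal
    residual force is below ``tol_force`` (torques below ``tol_force`` times
    the characteristic element length) and the kinetic energy is below
    ``tol_ke``; otherwise a non-converged result is returned. Divergence
    (non-finite state or runaway displacements) raises :class:`SolverFailure`
    carrying the last state.
    """
    params = params or SolverParams()
    comp = assembly.compile(axial_scale=params.axial_scale)
    constraints = list(assembly.point_constraints)
    pos = assembly.positions()
    quat = assembly.quaternions()
    fixed = assembly.fixed_mask()
    fixed_t, fixed_r = fixed[:, 0:3], fixed[:, 3:6]
    group = assembly.translation_groups()
    has_joints = len(assembly.joints) > 0
    if has_joints:
        pos = pos[group]  # joined nodes snap to their representative
    L = params.char_length or (float(np.mean(comp.l0)) if len(comp.l0) else 1.0)
    f_ext = np.zeros_like(pos) if external_forces is None else np.asarray(external_forces, float)
    m_ext = np.zeros_like(pos) if external_torques is None else np.asarray(external_torques, float)

    dt = params.dt
    m, I = _masses(comp, contact_env, constraints, params, dt)
    if has_joints:
        mg = np.zeros_like(m)
        np.add.at(mg, group, m)
        m = mg[group]
    v = np.zeros_like(pos)
    w = np.zeros_like(pos)
    ke_prev = 0.0
    contact_seen = False
    pos0 = pos.copy()
    kinetic = params.damping == "kinetic"
    zeta = 0.0 if kinetic else float(params.damping)
    energy = 0.0
    residual = np.inf
    ke = 0.0
    steps_done = 0

    for step in range(params.max_steps):
        F_int, M_int, energy, _ = internal_forces_compiled(comp, pos, quat)
        f = f_ext - F_int
        tq = m_ext - M_int
        for c in constraints:
            ids, per = c.forces(pos)
            np.add.at(f, ids, per)
        if contact_env is not None:
            pen, normal = contact_env.penetration(pos)
            active = pen > 0.0
            if np.any(active):
                vn = np.einsum("ij,ij->i", v, normal)
                fn = np.maximum(
                    0.0, contact_env.stiffness * pen + contact_env.damping * vn
                )
                fn[~active] = 0.0
                f -= fn[:, None] * normal
                if not contact_seen and np.any(fn > 0.0):
                    contact_seen = True
                    dt *= params.dt_contact_factor
                    m, I = _masses(comp, contact_env, constraints, params, dt)
                    v[:] = 0.0
                    w[:] = 0.0
        f[fixed_t] = 0.0
        tq[fixed_r] = 0.0
        if has_joints:
            fg = np.zeros_like(f)
            np.add.at(fg, group, f)
            f = fg[group]

        residual = max(
            float(np.linalg.norm(f, axis=1).max(initial=0.0)),
            float(np.linalg.norm(tq, axis=1).max(initial=0.0)) / L,
        )
        steps_done = step + 1
        if residual < params.tol_force and ke_prev < params.tol_ke:
            break

        a = f / m
        alpha = tq / I
        if kinetic:
            v += dt * a
            w += dt * alpha
        else:
            # per-node viscous damping at ratio zeta of the local frequency
            cd = zeta * 2.0 * np.sqrt(1.0 / params.mass_margin)  # c*dt/m
            v = (v * (1.0 - 0.5 * cd) + dt * a) / (1.0 + 0.5 * cd)
            w = (w * (1.0 - 0.5 * cd) + dt * alpha) / (1.0 + 0.5 * cd)
        v[fixed_t] = 0.0
        w[fixed_r] = 0.0
        ke = 0.5 * float(np.sum(m * v * v) + np.sum(I * w * w))
        if kinetic and ke < ke_prev:
            v[:] = 0.0
            w[:] = 0.0
            ke = 0.0
        ke_prev = ke
        pos = pos + dt * v
        if has_joints:
            pos = pos[group]
        quat = normalize_quat(quat_mul(rotvec_to_quat(w * dt), quat))

        if not np.all(np.isfinite(pos)) or np.abs(pos - pos0).max() > params.diverge_limit:
            raise SolverFailure("dynamic relaxation diverged", pos, quat)

    converged = residual < params.tol_force and ke_prev < params.tol_ke
    return EquilibriumResult(
        positions=pos,
        quats=quat,
        converged=converged,
        steps=steps_done,
        residual=residual,
        kinetic_energy=ke_prev,
        elastic_energy=energy,
        report={
            "dt_final": dt,
            "contact_triggered": contact_seen,
            "n_nodes": comp.n_nodes,
            "n_elements": len(comp.l0),
        },
    )


def solve_static_newton(
    assembly: BeamAssembly,
    external_forces: np.ndarray | None = None,
    external_torques: np.ndarray | None = None,
    tol_force: float = 1e-8,
    max_iter: int = 200,
    n_load_steps: int = 4,
) -> EquilibriumResult:
    """Damped Newton statics for small contact-free models.

    Uses the rotated material tangent (dense) with incremental load
    stepping and backtracking; intended for verification studies where the
    explicit relaxation step count would be dominated by fine-mesh stiffness
    contrast rather than by the quantity under test.
    """
    from .corotational import tangent_stiffness

    n = assembly.n_nodes
    pos = assembly.positions()
    quat = assembly.quaternions()
    fixed = assembly.fixed_mask().reshape(-1)
    free = ~fixed
    f_ext_full = np.zeros((n, 3)) if external_forces is None else np.asarray(external_forces, float)
    m_ext_full = np.zeros((n, 3)) if external_torques is None else np.asarray(external_torques, float)
    comp = assembly.compile()

    def residual_vec(pos, quat, scale):
        F_int, M_int, energy, _ = internal_forces_compiled(comp, pos, quat)
        r = np.zeros((n, 6))
        r[:, 0:3] = scale * f_ext_full - F_int
        r[:, 3:6] = scale * m_ext_full - M_int
        return r.reshape(-1), energy

    iters = 0
    for scale in np.linspace(1.0 / n_load_steps, 1.0, n_load_steps):
        for _ in range(max_iter):
            iters += 1
            r, energy = residual_vec(pos, quat, scale)
            rn = np.linalg.norm(r[free], np.inf)
            if rn < tol_force:
                break
            assembly.set_state(pos, quat)
            K = tangent_stiffness(assembly)
            d = np.zeros(6 * n)
            d[free] = np.linalg.solve(K[np.ix_(free, free)], r[free])
            step = 1.0
            for _ in range(30):
                dp = d.reshape(n, 6)
                pos_t = pos + step * dp[:, 0:3]
                quat_t = normalize_quat(
                    quat_mul(rotvec_to_quat(step * dp[:, 3:6]), quat)
                )
                r_t, _ = residual_vec(pos_t, quat_t, scale)
                if np.linalg.norm(r_t[free], np.inf) < rn:
                    pos, quat = pos_t, quat_t
                    break
                step *= 0.5
            else:
                break
    r, energy = residual_vec(pos, quat, 1.0)
    rn = float(np.linalg.norm(r[free], np.inf))
    assembly.set_state(pos, quat)
    return EquilibriumResult(
        positions=pos,
        quats=quat,
        converged=rn < tol_force,
        steps=iters,
        residual=rn,
        kinetic_energy=0.0,
        elastic_energy=energy,
        report={"solver": "newton"},
    )
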