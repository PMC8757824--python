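"""Corotational force recovery for 3D beam elements.

The deformed motion of each element is split into a large rigid transport of
a floating frame plus small local deformations. Local deformations are the
axial stretch and the end rotations measured relative to the current chord
frame; local forces follow from the elementary stiffness matrix and are
rotated back to the global frame. Internal forces vanish identically under
any rigid-body motion of the element.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from ._quat import mat_to_rotvec, quat_to_mat
from .assembly import BeamAssembly, CompiledAssembly, CorotationalElement, DegenerateGeometryError

_MIN_LENGTH = 1e-9


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def element_frames(
    comp: CompiledAssembly, pos: np.ndarray, Rn: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Current floating frames and end triads for every element.

    Returns (F, T1, T2, ln, e1) where F (E,3,3) has columns = frame axes.
    """
    d = pos[comp.n2] - pos[comp.n1]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln < _MIN_LENGTH):
        raise DegenerateGeometryError("collapsed beam element")
    e1 = d / ln[:, None]
    T1 = Rn[comp.n1] @ comp.R0
    T2 = Rn[comp.n2] @ comp.R0
    ym = T1[:, :, 1] + T2[:, :, 1]
    e3 = _cross(e1, ym)
    n3 = np.linalg.norm(e3, axis=1)
    bad = n3 < 1e-8
    if np.any(bad):
        # fall back to the end-frame z axis when the mean y axis degenerates
        e3[bad] = np.cross(e1[bad], T1[bad][:, :, 2])
        n3 = np.linalg.norm(e3, axis=1)
    e3 = e3 / n3[:, None]
    e2 = _cross(e3, e1)
    F = np.empty((len(ln), 3, 3))
    F[:, :, 0] = e1
    F[:, :, 1] = e2
    F[:, :, 2] = e3
    return F, T1, T2, ln, e1


def internal_forces_compiled(
    comp: CompiledAssembly, pos: np.ndarray, quat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Assembled internal forces/torques and elastic energy.

    Returns ``(F_int, M_int, energy, frames)`` with F_int, M_int of shape
    (n_nodes, 3): the forces the elements exert *on* their nodes enter the
    residual as ``f_ext - F_int``.
    """
    Rn = quat_to_mat(quat)
    F, T1, T2, ln, _ = element_frames(comp, pos, Rn)
    Ft = np.swapaxes(F, 1, 2)
    th1 = mat_to_rotvec(Ft @ T1)
    th2 = mat_to_rotvec(Ft @ T2)
    u = np.zeros((len(ln), 12))
    u[:, 3:6] = th1
    u[:, 6] = ln - comp.l0
    u[:, 9:12] = th2
    f_loc = np.einsum("eij,ej->ei", comp.K, u)
    energy = 0.5 * float(np.einsum("ei,ei->", u, f_loc))

    F_int = np.zeros((comp.n_nodes, 3))
    M_int = np.zeros((comp.n_nodes, 3))
    f1 = np.einsum("eij,ej->ei", F, f_loc[:, 0:3])
    m1 = np.einsum("eij,ej->ei", F, f_loc[:, 3:6])
    f2 = np.einsum("eij,ej->ei", F, f_loc[:, 6:9])
    m2 = np.einsum("eij,ej->ei", F, f_loc[:, 9:12])
    np.add.at(F_int, comp.n1, f1)
    np.add.at(M_int, comp.n1, m1)
    np.add.at(F_int, comp.n2, f2)
    np.add.at(M_int, comp.n2, m2)
    return F_int, M_int, energy, F


def internal_forces(
    element: CorotationalElement, states: list
) -> tuple[np.ndarray, np.ndarray]:
    """12-vector of global nodal forces/torques for one element.

    ``states`` is an indexable collection of :class:`NodeState`; the
    element's floating frame is updated in place. Layout of the returned
    vector: (f1, m1, f2, m2).
    """
    a = BeamAssembly()
    i, j = element.nodes
    a.add_node(states[i].position, states[i].rotation)
    a.add_node(states[j].position, states[j].rotation)
    a.elements.append(
        CorotationalElement((0, 1), element.l0, element.section, element.rest_frame)
    )
    comp = a.compile()
    F_int, M_int, _, frames = internal_forces_compiled(
        comp, a.positions(), a.quaternions()
    )
    element.floating_frame = frames[0]
    return (
        np.concatenate([F_int[0], M_int[0], F_int[1], M_int[1]]),
        frames[0],
    )


def elastic_energy(assembly: BeamAssembly) -> float:
    """Total elastic energy (N*mm) of the assembly in its current state."""
    comp = assembly.compile()
    return internal_forces_compiled(
        comp, assembly.positions(), assembly.quaternions()
    )[2]


def tangent_stiffness(assembly: BeamAssembly) -> np.ndarray:
    """Material tangent stiffness assembled in the current configuration.

    Rotates each elementary matrix by the current floating frame; symmetric
    by construction (geometric stiffness terms are omitted — the solver does
    not need them).
    """
    comp = assembly.compile()
    pos, quat = assembly.positions(), assembly.quaternions()
    Rn = Rotation.from_quat(quat).as_matrix()
    F, _, _, _, _ = element_frames(comp, pos, Rn)
    ndof = 6 * comp.n_nodes
    Kg = np.zeros((ndof, ndof))
    for e in range(len(comp.l0)):
        T = np.zeros((12, 12))
        for b in range(4):
            T[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = F[e].T
        Ke = T.T @ comp.K[e] @ T
        i, j = comp.n1[e], comp.n2[e]
        idx = np.r_[6 * i : 6 * i + 6, 6 * j : 6 * j + 6]
        Kg[np.ix_(idx, idx)] += Ke
    return Kg
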