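"""Local 12x12 stiffness matrix of a 3D two-node Timoshenko beam.

Local axes: x along the element, y/z transverse. DOF ordering per node is
(ux, uy, uz, rx, ry, rz), node 1 then node 2.
"""

from __future__ import annotations

import numpy as np

from .section import MaterialSection


def local_stiffness(
    section: MaterialSection,
    l: float,
    axial_scale: float = 1.0,
) -> np.ndarray:
    """Elementary stiffness matrix in local coordinates.

    Couples end displacements/rotations to end forces/torques:
    axial EA/l, torsion GJ/l, and shear-flexible bending blocks
    12EI/(l^3 (1+phi)), 6EI/(l^2 (1+phi)), (4+phi)EI/(l(1+phi)) and
    (2-phi)EI/(l(1+phi)). With phi = 0 this is the Euler-Bernoulli matrix.

    ``axial_scale`` multiplies the EA terms only; it is a numerical
    relaxation used by the equilibrium solver for inextensibility-dominated
    lattices and defaults to 1 (the exact matrix).
    """
    if not l > 0.0:
        raise ValueError("element length must be > 0")
    E, G = section.E, section.G
    A, Iy, Iz, J = section.A, section.Iy, section.Iz, section.J
    phi_y, phi_z = section.phi(l)

    K = np.zeros((12, 12))
    ax = axial_scale * E * A / l
    K[0, 0] = K[6, 6] = ax
    K[0, 6] = K[6, 0] = -ax
    t = G * J / l
    K[3, 3] = K[9, 9] = t
    K[3, 9] = K[9, 3] = -t

    def bend(i_u1, i_r1, i_u2, i_r2, I, phi, sign):
        # sign = +1 for bending in the x-y plane (rotation about z),
        # sign = -1 for the x-z plane (rotation about y).
        a = 12.0 * E * I / (l**3 * (1.0 + phi))
        b = sign * 6.0 * E * I / (l**2 * (1.0 + phi))
        c = (4.0 + phi) * E * I / (l * (1.0 + phi))
        d = (2.0 - phi) * E * I / (l * (1.0 + phi))
        K[i_u1, i_u1] = K[i_u2, i_u2] = a
        K[i_u1, i_u2] = K[i_u2, i_u1] = -a
        K[i_r1, i_r1] = K[i_r2, i_r2] = c
        K[i_r1, i_r2] = K[i_r2, i_r1] = d
        for iu, s in ((i_u1, 1.0), (i_u2, -1.0)):
            for ir in (i_r1, i_r2):
                K[iu, ir] = K[ir, iu] = s * b

    bend(1, 5, 7, 11, Iz, phi_y, +1.0)
    bend(2, 4, 8, 10, Iy, phi_z, -1.0)
    return K


def rigid_body_nullity(K: np.ndarray, rtol: float = 1e-8) -> int:
    """Number of (near-)zero eigenvalues of a symmetric stiffness matrix."""
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    scale = np.abs(w).max()
    return int(np.sum(np.abs(w) < rtol * scale))
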