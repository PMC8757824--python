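"""Node/element containers and the assembled beam model.

A :class:`BeamAssembly` is used both for the graft-centerline reduced model
(one beam per stent) and for full strut lattices. Nodes carry 6 DOF
(3 translations + 3 rotations, stored as rotation vectors and composed via
quaternions). Joints couple the translations of two nodes exactly (their
rotations stay independent), mimicking stents sewn to a common fabric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .section import MaterialSection
from .stiffness import local_stiffness


class DegenerateGeometryError(RuntimeError):
    """An element has collapsed (current length below tolerance)."""


@dataclass
class NodeState:
    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fixed_dofs: np.ndarray = field(default_factory=lambda: np.zeros(6, bool))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3)
        self.fixed_dofs = np.asarray(self.fixed_dofs, bool).reshape(6)


@dataclass
class CorotationalElement:
    """Two-node beam element with a floating (corotational) frame.

    ``rest_frame`` and ``floating_frame`` are 3x3 orthonormal triads whose
    *columns* are the local x (axial), y and z axes expressed in world
    coordinates. The floating frame follows the deformed element so that the
    motion from the reference configuration C_0 decomposes into a large rigid
    transport (C_0 -> C_S) times a small local deformation (C_S -> C_D).
    """

    nodes: tuple[int, int]
    l0: float
    section: MaterialSection
    rest_frame: np.ndarray
    floating_frame: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.l0 > 0.0:
            raise ValueError("rest length must be > 0")
        self.rest_frame = np.asarray(self.rest_frame, float).reshape(3, 3)
        R = self.rest_frame
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rest frame must be orthonormal")


def frame_from_axis(axis: np.ndarray) -> np.ndarray:
    """Orthonormal triad whose first column is ``axis`` (deterministic)."""
    e1 = np.asarray(axis, float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(helper, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


class BeamAssembly:
    """Collection of nodes, corotational elements, joints and constraints."""

    def __init__(self) -> None:
        self.nodes: list[NodeState] = []
        self.elements: list[CorotationalElement] = []
        self.joints: list[tuple[int, int]] = []
        self.point_constraints: list = []

    # -- construction -------------------------------------------------
    def add_node(self, position, rotation=None, fixed_dofs=None) -> int:
        self.nodes.append(
            NodeState(
                np.asarray(position, float),
                np.zeros(3) if rotation is None else rotation,
                np.zeros(6, bool) if fixed_dofs is None else fixed_dofs,
            )
        )
        return len(self.nodes) - 1

    def add_element(
        self,
        i: int,
        j: int,
        section: MaterialSection,
        rest_frame: np.ndarray | None = None,
        tag: str = "",
    ) -> int:
        d = self.nodes[j].position - self.nodes[i].position
        l0 = float(np.linalg.norm(d))
        if l0 <= 0.0:
            raise ValueError("coincident element nodes")
        if rest_frame is None:
            rest_frame = frame_from_axis(d)
        self.elements.append(
            CorotationalElement((i, j), l0, section, rest_frame, tag=tag)
        )
        return len(self.elements) - 1

    def add_joint(self, i: int, j: int) -> None:
        if i == j or not (0 <= i < len(self.nodes) and 0 <= j < len(self.nodes)):
            raise ValueError("joint must reference two distinct existing nodes")
        self.joints.append((i, j))

    # -- state accessors ----------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], float)

    def rotations(self) -> np.ndarray:
        return np.array([n.rotation for n in self.nodes], float)

    def quaternions(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotations()).as_quat()

    def fixed_mask(self) -> np.ndarray:
        return np.array([n.fixed_dofs for n in self.nodes], bool)

    def set_state(self, positions: np.ndarray, quats: np.ndarray) -> None:
        rv = Rotation.from_quat(quats).as_rotvec()
        for k, n in enumerate(self.nodes):
            n.position = positions[k].copy()
            n.rotation = rv[k].copy()

    def compile(self, axial_scale: float = 1.0) -> "CompiledAssembly":
        return CompiledAssembly(self, axial_scale=axial_scale)

    def translation_groups(self) -> np.ndarray:
        """Union-find representative per node for joint-coupled translations."""
        parent = np.arange(self.n_nodes)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in self.joints:
            parent[find(i)] = find(j)
        return np.array([find(k) for k in range(self.n_nodes)])


class CompiledAssembly:
    """Array-form view of an assembly for vectorized force evaluation."""

    def __init__(self, assembly: BeamAssembly, axial_scale: float = 1.0):
        self.assembly = assembly
        self.n_nodes = assembly.n_nodes
        self.n1 = np.array([e.nodes[0] for e in assembly.elements])
        self.n2 = np.array([e.nodes[1] for e in assembly.elements])
        self.l0 = np.array([e.l0 for e in assembly.elements])
        self.R0 = np.stack([e.rest_frame for e in assembly.elements])
        self.K = np.stack(
            [
                local_stiffness(e.section, e.l0, axial_scale=axial_scale)
                for e in assembly.elements
            ]
        )
        self.axial_scale = axial_scale

    def nodal_stiffness_estimates(self) -> tuple[np.ndarray, np.ndarray]:
        """Conservative per-node translational / rotational stiffness sums.

        Used for fictitious mass scaling in dynamic relaxation.
        """
        kt = np.zeros(self.n_nodes)
        kr = np.zeros(self.n_nodes)
        diag = np.einsum("eii->ei", self.K)
        k_trans = diag[:, 0:3].max(axis=1)
        k_rot = diag[:, 3:6].max(axis=1)
        np.add.at(kt, self.n1, k_trans)
        np.add.at(kt, self.n2, k_trans)
        np.add.at(kr, self.n1, k_rot)
        np.add.at(kr, self.n2, k_rot)
        return kt, kr
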