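"""Penalty constraints attaching nodes to geometric loci.

Used by Stage 1 (barycenter rays from the X-ray view) and by Stage 2
crimping (radial confinement to the launcher diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Locus:
    def closest_point(self, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PointLocus(Locus):
    point: np.ndarray

    def closest_point(self, p):
        return np.asarray(self.point, float)


@dataclass
class RayLocus(Locus):
    """Half-line origin + t*direction, t >= 0 (an X-ray back-projection ray)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)

    def closest_point(self, p):
        t = max(0.0, float((np.asarray(p) - self.origin) @ self.direction))
        return self.origin + t * self.direction


@dataclass
class PointConstraint:
    """Penalty spring from a node (or the midpoint of a node pair) to a locus.

    stiffness in N/mm. For a pair, the spring acts at the midpoint and the
    force is split evenly between the two nodes.
    """

    node_ids: tuple[int, ...]
    locus: Locus
    stiffness: float

    def forces(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(self.node_ids)
        p = pos[ids].mean(axis=0)
        f = self.stiffness * (self.locus.closest_point(p) - p)
        per = np.tile(f / len(ids), (len(ids), 1))
        return ids, per

    def stiffness_at(self, n_nodes: int) -> np.ndarray:
        k = np.zeros(n_nodes)
        k[np.asarray(self.node_ids)] = self.stiffness
        return k


@dataclass
class RadialConstraint:
    """Penalty pulling nodes toward a target radius about an axis.

    Drives crimping: targets can be re-set between solver phases to ramp the
    device down to the launcher diameter.
    """

    node_ids: np.ndarray
    axis_point: np.ndarray
    axis_dir: np.ndarray
    target_radii: np.ndarray
    stiffness: float
    one_sided: bool = False  # only push inward when True

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, int)
        self.axis_point = np.asarray(self.axis_point, float)
        d = np.asarray(self.axis_dir, float)
        self.axis_dir = d / np.linalg.norm(d)
        self.target_radii = np.broadcast_to(
            np.asarray(self.target_radii, float), self.node_ids.shape
        ).copy()

    def forces(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = pos[self.node_ids] - self.axis_point
        ax = (p @ self.axis_dir)[:, None] * self.axis_dir
        rad = p - ax
        r = np.linalg.norm(rad, axis=1)
        rhat = np.divide(rad, r[:, None], out=np.zeros_like(rad), where=r[:, None] > 1e-12)
        dr = self.target_radii - r
        if self.one_sided:
            dr = np.minimum(dr, 0.0)
        return self.node_ids, self.stiffness * dr[:, None] * rhat

    def stiffness_at(self, n_nodes: int) -> np.ndarray:
        k = np.zeros(n_nodes)
        k[self.node_ids] = self.stiffness
        return k
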