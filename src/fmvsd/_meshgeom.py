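"""Exact point-to-mesh queries (closest triangle, containment).

Self-contained vectorized implementations used by the vessel module:
closest points via candidate pruning on a triangle-centroid KD-tree with an
exactness radius, and inside/outside via the generalized winding number
(robust for watertight meshes, no ray casting).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(tri: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to the point ``pts[i]``.

    Classic region-based projection onto the triangle's plane with edge
    clamping (Eberly). Shapes: tri (n, 3, 3), pts (n, 3) -> (n, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = pts - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = pts - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = pts - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(pts)
    done = np.zeros(len(pts), bool)

    def settle(mask, val):
        m = mask & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)

    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b + np.nan_to_num(w_bc)[:, None] * (c - b),
    )

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    interior = a + np.nan_to_num(v)[:, None] * ab + np.nan_to_num(w)[:, None] * ac
    settle(np.ones(len(pts), bool), interior)
    return out


class MeshDistance:
    """Exact nearest-triangle queries against a fixed triangle soup."""

    def __init__(self, triangles: np.ndarray):
        self.tri = np.asarray(triangles, float)
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        # exactness radius: a triangle can only beat a candidate if its
        # centroid is within best_distance + its own circumscribing reach
        self.reach = float(
            np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max()
        )

    def query(self, pts: np.ndarray, k0: int = 8) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(pts, float))
        k0 = min(k0, len(self.centroids))
        _, cand = self.tree.query(pts, k=k0)
        cand = np.atleast_2d(cand)
        n = len(pts)
        rep = np.repeat(np.arange(n), cand.shape[1])
        cp0 = closest_point_on_triangles(self.tri[cand.ravel()], pts[rep])
        d0 = np.linalg.norm(cp0 - pts[rep], axis=1).reshape(n, -1)
        best = d0.min(axis=1)
        arg = d0.argmin(axis=1)
        closest = cp0.reshape(n, -1, 3)[np.arange(n), arg]
        # widen to every triangle that could still be closer
        balls = self.tree.query_ball_point(pts, best + self.reach + 1e-12)
        for i, faces in enumerate(balls):
            faces = np.asarray(faces)
            if len(faces) <= k0:
                continue
            cp = closest_point_on_triangles(self.tri[faces], np.tile(pts[i], (len(faces), 1)))
            d = np.linalg.norm(cp - pts[i], axis=1)
            j = d.argmin()
            if d[j] < best[i]:
                best[i] = d[j]
                closest[i] = cp[j]
        return best, closest


def winding_numbers(mesh, pts: np.ndarray, chunk: int | None = None) -> np.ndarray:
    """Generalized winding number of each point (≈1 inside, ≈0 outside)."""
    tri = mesh.triangles
    pts = np.atleast_2d(np.asarray(pts, float))
    if chunk is None:
        # keep the (chunk, faces, 3) temporaries around ~100 MB
        chunk = max(1, int(4e6 / max(len(tri), 1)))
    out = np.empty(len(pts))
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        omega = 2.0 * np.arctan2(det, denom)
        out[s : s + chunk] = omega.sum(axis=1) / (4.0 * np.pi)
    return out


def mesh_contains(mesh, pts: np.ndarray) -> np.ndarray:
    return np.abs(winding_numbers(mesh, pts)) > 0.5
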