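"""Minimal legacy-VTK ASCII export for rendering results.

Deployed stents are written as poly-lines with a radius attribute; the
merged export bundles the vessel surface triangles and every stent wire in
one file so standard viewers can render the scene directly.
"""

from __future__ import annotations

import numpy as np


def save_polylines_vtk(path, polylines: list[np.ndarray], radius: float = 0.0625) -> None:
    pts = np.vstack(polylines)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfmvsd stent wires\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(pl) + 1 for pl in polylines)
        fh.write(f"LINES {len(polylines)} {total}\n")
        off = 0
        for pl in polylines:
            fh.write(" ".join([str(len(pl))] + [str(off + k) for k in range(len(pl))]) + "\n")
            off += len(pl)
        fh.write(f"POINT_DATA {len(pts)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for _ in range(len(pts)):
            fh.write(f"{radius:.6f}\n")


def save_merged_vtk(path, vessel_mesh, polylines: list[np.ndarray]) -> None:
    """Vessel surface + stent wires in a single unstructured grid."""
    vpts = np.asarray(vessel_mesh.vertices)
    faces = np.asarray(vessel_mesh.faces)
    wire_pts = np.vstack(polylines) if polylines else np.zeros((0, 3))
    pts = np.vstack([vpts, wire_pts])
    cells = []
    for f in faces:
        cells.append([5, 3, *f])  # VTK_TRIANGLE
    off = len(vpts)
    for pl in polylines:
        cells.append([4, len(pl), *(off + k for k in range(len(pl)))])  # VTK_POLY_LINE
        off += len(pl)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfmvsd merged scene\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        n_items = sum(len(c) - 1 for c in cells)
        fh.write(f"CELLS {len(cells)} {n_items}\n")
        for c in cells:
            fh.write(" ".join(str(v) for v in c[1:]) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for c in cells:
            fh.write(f"{c[0]}\n")
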