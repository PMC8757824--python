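"""JSON round-trip of beam assemblies (debugging and fixtures)."""

from __future__ import annotations

import json

import numpy as np

from .assembly import BeamAssembly, CorotationalElement
from .section import MaterialSection


def assembly_to_dict(a: BeamAssembly) -> dict:
    return {
        "nodes": [
            {
                "position": n.position.tolist(),
                "rotation": n.rotation.tolist(),
                "fixed_dofs": n.fixed_dofs.astype(int).tolist(),
            }
            for n in a.nodes
        ],
        "elements": [
            {
                "nodes": list(e.nodes),
                "l0": e.l0,
                "rest_frame": e.rest_frame.tolist(),
                "tag": e.tag,
                "section": {
                    k: getattr(e.section, k)
                    for k in ("E", "nu", "A", "Iy", "Iz", "J", "Asy", "Asz")
                },
            }
            for e in a.elements
        ],
        "joints": [list(j) for j in a.joints],
    }


def assembly_from_dict(d: dict) -> BeamAssembly:
    a = BeamAssembly()
    for n in d["nodes"]:
        a.add_node(n["position"], n["rotation"], np.array(n["fixed_dofs"], bool))
    for e in d["elements"]:
        sec = MaterialSection(**e["section"])
        a.elements.append(
            CorotationalElement(
                tuple(e["nodes"]), e["l0"], sec, np.array(e["rest_frame"]), tag=e.get("tag", "")
            )
        )
    for j in d.get("joints", []):
        a.add_joint(*j)
    return a


def save_assembly(a: BeamAssembly, path) -> None:
    with open(path, "w") as fh:
        json.dump(assembly_to_dict(a), fh)


def load_assembly(path) -> BeamAssembly:
    with open(path) as fh:
        return assembly_from_dict(json.load(fh))
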