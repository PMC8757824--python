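"""Reference evaluation suite: seeded synthetic study conditions.

Five scenes emulate the validation settings the method targets — straight
and curved vessels, an oversized rigid-sac phantom, a fenestrated device
with radiopaque markers, and a patient-like moderate aneurysm — each run
end-to-end (Stage 1 + Stage 2 on every stent) and scored against the
generator's ground truth with D_B, D_PC and fenestration distances.
"""

from __future__ import annotations

import numpy as np

from .pipeline import case_from_scene, run_fmvsd
from .synthetic import build_scene, preset_scene

SUITE_SCENES = ("straight", "curved", "sac_phantom", "fenestrated", "patient_sac")


def run_study_suite(seed: int = 0, scenes=SUITE_SCENES) -> dict[str, dict]:
    """Run the full two-stage method on every suite scene.

    Per-scene seeds are derived from the master seed; each report carries
    per-stent D_B/D_PC, fenestration distances, rotations and timings.
    """
    reports = {}
    for k, name in enumerate(scenes):
        scene_seed = (seed * 1_000_003 + 7 * k + 1) % (2**31 - 1)
        scene = build_scene(preset_scene(name, seed=scene_seed))
        case = case_from_scene(scene)
        reports[name] = run_fmvsd(case, seed=scene_seed)
    return reports


def suite_error_maxima(reports: dict[str, dict]) -> dict[str, float]:
    """Maxima over all stents, cases and fenestrations of the suite."""
    db = [e["D_B"] for r in reports.values() for e in r["errors"]]
    dpc = [e["D_PC"] for r in reports.values() for e in r["errors"]]
    fen = [
        d
        for r in reports.values()
        for d in (r.get("fenestration_distances_mm") or [])
    ]
    out = {
        "max_D_B_mm": float(np.max(db)),
        "max_D_PC_mm": float(np.max(dpc)),
        "n_stents": len(db),
        "n_fenestrations": len(fen),
    }
    out["max_fenestration_mm"] = float(np.max(fen)) if fen else float("nan")
    out["max_overall_mm"] = float(
        np.max(db + dpc + fen) if fen else np.max(db + dpc)
    )
    return out
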