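"""Pipeline orchestration: Stage 1 + Stage 2 + evaluation on a case.

A case bundles the four inputs (vessel + centerline, device spec,
calibrated projection, per-stent observations or target image + masks) and
optionally the ground truth for evaluation. ``run_fmvsd`` always runs
Stage 1 and the Stage-2 rotation recovery; Stage-2 individual deployment
runs on a configurable stent subset (default: all). A per-stent Stage-2
failure degrades gracefully to that stent's Stage-1 reconstruction.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .devices import (
    GraftSpec,
    StentMesh,
    build_centerline_assembly,
    build_zstent_mesh,
    load_graft,
    place_fenestration_points,
    stent_pose_transform,
)
from .fem import SolverFailure
from .imaging import (
    ProjectionModel,
    TargetObservation,
    back_project_hull,
    load_observations,
)
from .metrics import StentError, case_summary, fenestration_distance
from .stage1 import position_centerline, reconstruct_stent
from .stage2 import deploy_stent, recover_rotation
from .vessel import VesselMesh, build_deployment_box
from .vtkio import save_merged_vtk


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class Case:
    graft: GraftSpec
    vessel: VesselMesh
    projection: ProjectionModel
    observations: list[TargetObservation]
    truth: dict | None = None
    mesh_sizes: tuple[float, float] = (1.5, 0.4)
    name: str = "case"
    stent_meshes: list[StentMesh] = field(default_factory=list)

    def __post_init__(self):
        if not self.stent_meshes:
            self.stent_meshes = [
                build_zstent_mesh(s, self.mesh_sizes) for s in self.graft.stents
            ]


def load_case(case_dir, mesh_sizes=(1.5, 0.4)) -> Case:
    """Load the fixed case-directory layout (see synthetic.write_case)."""
    d = Path(case_dir)
    for required in ("device.yaml", "projection.json", "vessel.stl", "observations.json"):
        if not (d / required).exists():
            raise MissingInputError(f"case input missing: {required}")
    graft = load_graft(d / "device.yaml")
    projection = ProjectionModel.load(d / "projection.json")
    cl = np.zeros((0, 3))
    radii = np.zeros(0)
    if (d / "centerline.txt").exists():
        data = np.loadtxt(d / "centerline.txt")
        cl, radii = data[:, :3], data[:, 3]
    vessel = VesselMesh.from_file(d / "vessel.stl", centerline=cl, radii=radii)
    observations = load_observations(d / "observations.json")
    if (d / "masks.png").exists():
        import imageio.v3 as iio

        labels = iio.imread(d / "masks.png")
        for i, obs in enumerate(observations):
            yy, xx = np.nonzero(labels == i + 1)
            if len(xx):
                obs.pixel_set = np.column_stack([xx, yy]).astype(float)
    truth = None
    if (d / "truth.json").exists():
        with open(d / "truth.json") as fh:
            truth = json.load(fh)
    return Case(
        graft=graft,
        vessel=vessel,
        projection=projection,
        observations=observations,
        truth=truth,
        mesh_sizes=mesh_sizes,
        name=d.name,
    )


def case_from_scene(scene) -> Case:
    """In-memory case from a synthetic scene (no file round trip)."""
    truth = {
        "stents": [
            {
                "center": t.center.tolist(),
                "triad": np.asarray(t.triad).tolist(),
                "phi": t.phi,
                "cloud": t.cloud,
            }
            for t in scene.truths
        ],
        "fenestrations": [
            {"stent": f.stent_index, "centroid": f.centroid, "rim": f.rim}
            for f in scene.fenestrations_true
        ],
    }
    return Case(
        graft=scene.graft,
        vessel=scene.vessel,
        projection=scene.projection,
        observations=scene.observations,
        truth=truth,
        mesh_sizes=scene.spec.mesh_sizes,
        name=scene.spec.name,
        stent_meshes=scene.stent_meshes,
    )


def run_fmvsd(
    case: Case,
    stage2_subset="all",
    seed: int = 0,
    use_markers: bool = True,
    box_resolution: float = 0.75,
    merged_vtk_path=None,
) -> dict:
    """Run the full two-stage method on one case.

    Returns a JSON-serializable report with per-stent poses, rotations,
    deployed clouds (held separately), and per-stent errors when ground
    truth is available. Deterministic for a fixed seed.
    """
    t_start = time.time()
    graft, projection, vessel = case.graft, case.projection, case.vessel
    n = graft.n_stents
    if len(case.observations) != n:
        raise MissingInputError(
            f"{n} stents in device but {len(case.observations)} observations"
        )
    subset = set(range(n)) if stage2_subset == "all" else set(stage2_subset)
    timings = {}

    # ---- Stage 1: global positioning + geometric reconstruction ----
    t0 = time.time()
    assembly = build_centerline_assembly(graft)
    s1 = position_centerline(
        assembly, case.observations, projection, vessel, graft
    )
    clouds = []
    diam_meas_mm = []
    for i, mesh in enumerate(case.stent_meshes):
        mag = projection.magnification(s1.barycenters[i])
        obs = case.observations[i]
        wire_px = graft.stents[i].wire_diameter * mag
        dp = max((obs.apparent_diam_proximal - wire_px) / mag, 1.0)
        dd = max((obs.apparent_diam_distal - wire_px) / mag, 1.0)
        diam_meas_mm.append((dp, dd))
        clouds.append(
            reconstruct_stent(mesh, s1.barycenters[i], s1.triads[i], dp, dd)
        )
    timings["stage1_s"] = time.time() - t0

    # ---- Stage 2 step 1: rotation recovery for every stent ----
    t0 = time.time()
    marked = {}
    for sid, p in graft.markers:
        marked.setdefault(sid, []).append(p)
    rotations = []
    for i, mesh in enumerate(case.stent_meshes):
        obs = case.observations[i]
        bary_dev = np.array([0.0, 0.0, graft.stents[i].axial_position])
        markers_local = None
        if use_markers and i in marked and len(obs.marker_points2d) >= 2:
            markers_local = np.vstack(marked[i]) - bary_dev
        dp, dd = diam_meas_mm[i]
        s = graft.stents[i]
        scale = 0.5 * (dp / s.diameter_proximal + dd / s.diameter_distal)
        V = mesh.V.copy()
        V[:, :2] *= scale  # rotate the *reconstructed* (scaled) cloud
        try:
            rot = recover_rotation(
                V,
                s1.barycenters[i],
                s1.triads[i],
                obs,
                projection,
                n_peaks=s.n_peaks,
                markers_local=markers_local,
                seed=(seed * 1009 + i) % (2**31 - 1),
            )
        except ValueError as exc:
            warnings.warn(f"rotation recovery failed for stent {i}: {exc}")
            from .stage2 import RotationResult

            rot = RotationResult(0.0, float("nan"), "failed", 2 * math.pi)
        rotations.append(rot)
    timings["rotation_s"] = time.time() - t0

    # ---- Stage 2 step 2: individual deployment in rigid boxes ----
    t0 = time.time()
    depths = projection.depth(vessel.mesh.vertices)
    span = depths.max() - depths.min()
    depth_range = (
        max(depths.min() - 0.1 * span, 1e-3),
        depths.max() + 0.1 * span,
    )
    deployed = {}
    stage2_log = {}
    for i in sorted(subset):
        try:
            poly = back_project_hull(projection, case.observations[i].hull2d, depth_range)
            box = build_deployment_box(
                vessel, poly, resolution=box_resolution, provenance={"stent": i}
            )
            dep = deploy_stent(
                case.stent_meshes[i],
                rotations[i].phi,
                s1.barycenters[i],
                s1.triads[i],
                graft.launcher_diameter,
                box,
            )
            deployed[i] = dep
            stage2_log[i] = dep.report
        except (SolverFailure, ValueError, RuntimeError) as exc:
            warnings.warn(f"stage 2 failed for stent {i}; keeping stage 1 result ({exc})")
            stage2_log[i] = {"failed": str(exc)}
    timings["stage2_s"] = time.time() - t0

    final_clouds = [
        deployed[i].cloud if i in deployed else clouds[i] for i in range(n)
    ]

    # ---- simulated fenestration positions ----
    fens_dev, _ = place_fenestration_points(graft)
    fens_sim = []
    for f in fens_dev:
        i = f.stent_index
        fens_sim.append(
            {
                "stent": i,
                "centroid": stent_pose_transform(
                    f.centroid, graft.stents[i], s1.barycenters[i], s1.triads[i], rotations[i].phi
                )[0],
            }
        )

    # ---- evaluation against ground truth ----
    errors = None
    fen_dists = None
    summary = None
    if case.truth is not None:
        errors = [
            StentError.from_clouds(
                i, final_clouds[i], np.asarray(case.truth["stents"][i]["cloud"], float)
            )
            for i in range(n)
        ]
        summary = case_summary(errors)
        fen_dists = []
        for sim, true in zip(fens_sim, case.truth.get("fenestrations", [])):
            fen_dists.append(
                fenestration_distance(sim["centroid"], np.asarray(true["centroid"], float))
            )
    timings["total_s"] = time.time() - t_start

    if merged_vtk_path is not None:
        lines = [final_clouds[i] for i in range(n)]
        save_merged_vtk(merged_vtk_path, vessel.mesh, lines)

    report = {
        "case": case.name,
        "seed": seed,
        "n_stents": n,
        "stage2_subset": sorted(subset),
        "stage1": {
            "barycenters": s1.barycenters.tolist(),
            "triads": [np.asarray(t).tolist() for t in s1.triads],
            "residual_px": s1.residual_px.tolist(),
            "converged": bool(s1.converged),
            "measured_diameters_mm": diam_meas_mm,
        },
        "rotations": [
            {"phi": r.phi, "residual": r.residual, "mode": r.mode, "theta": r.theta}
            for r in rotations
        ],
        "stage2": {str(k): v for k, v in stage2_log.items()},
        "fenestrations_sim": [
            {"stent": f["stent"], "centroid": np.asarray(f["centroid"]).tolist()}
            for f in fens_sim
        ],
        "timings": timings,
    }
    if errors is not None:
        report["errors"] = [
            {
                "stent_id": e.stent_id,
                "D_B": e.D_B,
                "D_PC": e.D_PC,
                "quality_B": e.quality_B.value,
                "quality_PC": e.quality_PC.value,
            }
            for e in errors
        ]
        report["summary"] = summary
        report["fenestration_distances_mm"] = fen_dists
    report["_clouds"] = final_clouds  # in-memory only; stripped on save
    return report


def save_report(report: dict, path) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2)
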