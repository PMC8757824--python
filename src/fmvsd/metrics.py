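"""Evaluation measures: D_B, D_PC, fenestration distances, quality classes.

D_B is the Euclidean distance between the 3D barycenters of the simulated
and target stent point clouds (positioning error). D_PC is the *directed*
mean nearest-neighbour distance from the simulated cloud to the target
cloud (positioning + deployment error); it is deliberately not symmetrized.
Simulation quality: excellent below 3 mm, good below 5 mm, insufficient at
or above 5 mm (exact 3/5 mm boundaries are assigned upward).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

EXCELLENT_MM = 3.0
GOOD_MM = 5.0


class Quality(str, Enum):
    excellent = "excellent"
    good = "good"
    insufficient = "insufficient"


def classify(D: float) -> Quality:
    """Quality class of a distance in mm."""
    if D < 0:
        raise ValueError("distance must be >= 0")
    if D < EXCELLENT_MM:
        return Quality.excellent
    if D < GOOD_MM:
        return Quality.good
    return Quality.insufficient


def barycenter_distance(sim_cloud: np.ndarray, target_cloud: np.ndarray) -> float:
    """D_B: distance between the means of the two clouds (mm)."""
    a = np.asarray(sim_cloud, float)
    b = np.asarray(target_cloud, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("clouds must be non-empty")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


def point_cloud_distance(sim_cloud: np.ndarray, target_cloud: np.ndarray) -> float:
    """D_PC: mean distance from each simulated point to its nearest target
    neighbour (mm); directed, simulated -> target."""
    a = np.asarray(sim_cloud, float)
    b = np.asarray(target_cloud, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("clouds must be non-empty")
    d, _ = cKDTree(b).query(a)
    return float(np.mean(d))


def fenestration_distance(sim_centroid: np.ndarray, target_centroid: np.ndarray) -> float:
    """Distance between simulated and target fenestration rim centroids."""
    return float(np.linalg.norm(np.asarray(sim_centroid) - np.asarray(target_centroid)))


@dataclass
class StentError:
    stent_id: int
    D_B: float
    D_PC: float
    quality_B: Quality
    quality_PC: Quality
    excluded: bool = False  # e.g. stents overlapping in projection

    @classmethod
    def from_clouds(cls, stent_id, sim_cloud, target_cloud, excluded=False) -> "StentError":
        db = barycenter_distance(sim_cloud, target_cloud)
        dpc = point_cloud_distance(sim_cloud, target_cloud)
        return cls(stent_id, db, dpc, classify(db), classify(dpc), excluded)


def case_summary(errors: list[StentError]) -> dict:
    """Per-case mean/std/max/min of D_B and D_PC over included stents."""
    inc = [e for e in errors if not e.excluded]
    out = {}
    for key in ("D_B", "D_PC"):
        v = np.array([getattr(e, key) for e in inc])
        out[key] = {
            "mean": float(v.mean()),
            "std": float(v.std(ddof=0)),
            "max": float(v.max()),
            "min": float(v.min()),
        }
    out["n_stents"] = len(inc)
    return out


def write_report(errors: list[StentError], summary: dict, json_path=None, csv_path=None):
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "stents": [
                        {**asdict(e), "quality_B": e.quality_B.value, "quality_PC": e.quality_PC.value}
                        for e in errors
                    ],
                    "summary": summary,
                },
                fh,
                indent=2,
            )
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stent_id", "D_B", "D_PC", "quality_B", "quality_PC", "excluded"])
            for e in errors:
                w.writerow(
                    [e.stent_id, e.D_B, e.D_PC, e.quality_B.value, e.quality_PC.value, e.excluded]
                )


def distance_map_figure(case_errors: dict[str, list[StentError]], path=None):
    """Distance-map style summary: one row per case, one square per stent."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 3))
    names = list(case_errors)
    nmax = max(len(v) for v in case_errors.values())
    for ax, key in zip(axes, ("D_B", "D_PC")):
        grid = np.full((len(names), nmax), np.nan)
        for r, nm in enumerate(names):
            for e in case_errors[nm]:
                if not e.excluded:
                    grid[r, e.stent_id] = getattr(e, key)
        im = ax.imshow(grid, cmap="viridis", vmin=0, vmax=GOOD_MM)
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("stent")
        ax.set_title(f"{key} (mm)")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
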