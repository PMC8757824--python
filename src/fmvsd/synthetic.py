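"""Synthetic phantom/clinical scene generator.

Stands in for the two validation settings the method targets: a rigid
aneurysm phantom (oversized fusiform sac) and patient-like cases (curved,
moderately aneurysmal aortas). Every scene provides the four pipeline
inputs — vessel surface + centerline, device spec, calibrated projection,
and a rendered single-view target with per-stent pixel labels and
radiopaque-marker dots — plus the ground truth the metrics compare against:
per-stent deployed point clouds obtained by relaxing each strut model
against the true vessel wall at its true pose.

Determinism: everything derives from ``SceneSpec.seed``; identical specs
produce identical scenes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage

from .devices import (
    FenestrationPoints,
    GraftSpec,
    StentMesh,
    build_zstent_mesh,
    load_graft,
    place_fenestration_points,
    pose_assembly,
    resample_deployed_cloud,
    save_graft,
    stent_pose_transform,
)
from .fem import ContactEnvironment, SolverParams, solve_equilibrium
from .imaging import ProjectionModel, TargetObservation, make_observation, save_observations
from .vessel import TubeSDF, VesselMesh


class SceneError(ValueError):
    pass


@dataclass
class SceneSpec:
    """Parameters of one synthetic single-view deployment scene.

    The vessel is a tube of revolution around a (possibly bowed) centerline
    with an optional fusiform aneurysm bulge. The device's true path
    follows the vessel centerline, with an optional extra out-of-plane
    offset inside the sac (``sac_device_offset``, along the viewing axis)
    emulating the unconstrained positioning of a stent-graft in an
    oversized rigid sac.
    """

    device: str = "synthetic_main_body_28_13"
    seed: int = 0
    proximal_radius: float = 12.0
    distal_radius: float = 10.0
    aneurysm_max_radius: float | None = None
    sac_center: float | None = None  # mm along the device axis
    sac_length: float = 60.0
    bend_amplitude: float = 0.0  # in-plane centerline bow (mm)
    sac_device_offset: float = 0.0  # out-of-plane device bow in the sac (mm)
    margin: float = 15.0  # vessel extension beyond the device ends (mm)
    mesh_sizes: tuple[float, float] = (1.5, 0.4)
    image_size: tuple[int, int] = (512, 512)
    pixel_spacing: float = 0.6
    blur_sigma: float = 0.0
    noise: float = 0.0
    phi_true: list[float] | None = None
    name: str = "scene"

    def __post_init__(self):
        if self.aneurysm_max_radius is not None:
            if self.aneurysm_max_radius < max(self.proximal_radius, self.distal_radius):
                raise SceneError("aneurysm radius must exceed the healthy radius")


@dataclass
class StentTruth:
    center: np.ndarray  # true pose barycenter (world mm)
    triad: np.ndarray  # true pose axes (columns)
    phi: float
    cloud: np.ndarray  # deployed ground-truth point cloud (world mm)


@dataclass
class SyntheticScene:
    spec: SceneSpec
    graft: GraftSpec
    vessel: VesselMesh
    projection: ProjectionModel
    stent_meshes: list[StentMesh]
    truths: list[StentTruth]
    fenestrations_true: list[FenestrationPoints]
    markers_true: list[tuple[int, np.ndarray]]
    image: np.ndarray = field(default=None)
    masks: list[np.ndarray] = field(default_factory=list)
    observations: list[TargetObservation] = field(default_factory=list)


# ----------------------------------------------------------------------
# Vessel generation
# ----------------------------------------------------------------------


def _centerline(spec: SceneSpec, z0: float, z1: float, n: int = 121):
    z = np.linspace(z0, z1, n)
    L = z1 - z0
    y = spec.bend_amplitude * np.sin(math.pi * (z - z0) / L)
    pts = np.column_stack([np.zeros_like(z), y, z])
    seg = np.diff(pts, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) < 1e-9):
        raise SceneError("self-intersecting centerline")
    return pts, z


def _radius_profile(spec: SceneSpec, z: np.ndarray, z0: float, z1: float):
    t = (z - z0) / (z1 - z0)
    r = spec.proximal_radius + t * (spec.distal_radius - spec.proximal_radius)
    if spec.aneurysm_max_radius is not None:
        zc = spec.sac_center if spec.sac_center is not None else 0.5 * (z0 + z1)
        base_at = np.interp(zc, z, r) if len(np.atleast_1d(z)) > 1 else r
        bump = (spec.aneurysm_max_radius - base_at) * np.exp(
            -(((z - zc) / (spec.sac_length / 4.0)) ** 2)
        )
        r = r + bump
    return r


def make_vessel(spec: SceneSpec, z0: float, z1: float, n_theta: int = 64) -> VesselMesh:
    """Watertight tube of revolution with optional bend and fusiform sac."""
    cl, z = _centerline(spec, z0, z1)
    r = _radius_profile(spec, z, z0, z1)
    # parallel-transported frames along the centerline
    tangents = np.gradient(cl, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    u = np.array([1.0, 0.0, 0.0])
    u = u - (u @ tangents[0]) * tangents[0]
    u /= np.linalg.norm(u)
    frames = []
    for k, t in enumerate(tangents):
        if k > 0:
            u = u - (u @ t) * t
            u /= np.linalg.norm(u)
        frames.append((u.copy(), np.cross(t, u)))
    theta = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    rings = np.array(
        [
            cl[k]
            + r[k] * (np.outer(np.cos(theta), frames[k][0]) + np.outer(np.sin(theta), frames[k][1]))
            for k in range(len(z))
        ]
    )
    nv = len(z)
    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(nv - 1):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            a, b = k * n_theta + j, k * n_theta + j2
            c, d = (k + 1) * n_theta + j, (k + 1) * n_theta + j2
            faces.append([a, b, d])
            faces.append([a, d, c])
    # cap centers
    verts = np.vstack([verts, cl[0], cl[-1]])
    i0, i1 = len(verts) - 2, len(verts) - 1
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        faces.append([i0, j2, j])
        faces.append([i1, (nv - 1) * n_theta + j, (nv - 1) * n_theta + j2])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return VesselMesh(mesh=mesh, centerline=cl, radii=r, analytic_sdf=TubeSDF(cl, r))


# ----------------------------------------------------------------------
# Device true pose
# ----------------------------------------------------------------------


def device_path(scene_spec: SceneSpec, graft: GraftSpec, z0: float, z1: float):
    """True pose (center, triad) per stent along the vessel centerline.

    Adds the out-of-plane sac offset where the sac is; triads are
    parallel-transported so the device twists smoothly.
    """
    cl, z = _centerline(scene_spec, z0, z1)
    if scene_spec.aneurysm_max_radius is not None and scene_spec.sac_device_offset:
        zc = scene_spec.sac_center if scene_spec.sac_center is not None else 0.5 * (z0 + z1)
        bump = np.exp(-(((z - zc) / (scene_spec.sac_length / 4.0)) ** 2))
        cl = cl + scene_spec.sac_device_offset * np.column_stack(
            [bump, np.zeros_like(z), np.zeros_like(z)]
        )
    tangents = np.gradient(cl, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    u = np.array([1.0, 0.0, 0.0])
    u -= (u @ tangents[0]) * tangents[0]
    u /= np.linalg.norm(u)
    centers, triads = [], []
    for s in graft.stents:
        zk = s.axial_position
        k = int(np.argmin(np.abs(z - zk)))
        # transport u from the start to sample k
        uu = u.copy()
        for t in tangents[1 : k + 1]:
            uu = uu - (uu @ t) * t
            uu /= np.linalg.norm(uu)
        t = tangents[k]
        c = cl[k] + (zk - z[k]) * t
        triads.append(np.column_stack([uu, np.cross(t, uu), t]))
        centers.append(c)
    return np.array(centers), triads


# ----------------------------------------------------------------------
# Ground-truth deployment
# ----------------------------------------------------------------------


def make_ground_truth(
    scene_spec: SceneSpec,
    graft: GraftSpec,
    vessel: VesselMesh,
    stent_meshes: list[StentMesh],
    centers: np.ndarray,
    triads: list[np.ndarray],
    phis: np.ndarray,
    solver_params: SolverParams | None = None,
) -> list[StentTruth]:
    """Deploy every stent against the true vessel wall at its true pose.

    The purely elastic strut model makes the equilibrium path-independent,
    so deployment starts from the nominal ring (no crimp phase here).
    """
    params = solver_params or SolverParams(
        axial_scale=1e-3, tol_force=2e-4, tol_ke=1e-8, max_steps=20000
    )
    truths = []
    for i, mesh in enumerate(stent_meshes):
        asm = pose_assembly(mesh, centers[i], triads[i], phis[i])
        env = ContactEnvironment(
            vessel.sdf(),
            stiffness=5.0,
            damping=0.05,
            offset=mesh.spec.wire_diameter / 2.0,
        )
        res = solve_equilibrium(asm, contact_env=env, params=params)
        cloud = resample_deployed_cloud(mesh, res.positions, scene_spec.mesh_sizes[1])
        truths.append(
            StentTruth(center=centers[i], triad=triads[i], phi=float(phis[i]), cloud=cloud)
        )
    return truths


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------


def _disc(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def render_projection(
    scene_spec: SceneSpec,
    projection: ProjectionModel,
    truths: list[StentTruth],
    markers_world: list[tuple[int, np.ndarray]],
    rng: np.random.Generator,
):
    """Forward-project the ground truth into a synthetic fluoroscopy target.

    Struts are splatted with their magnified wire width; markers are
    Gaussian dots brighter than the struts; polarity is bright metal on a
    dark background. Per-stent pixel labels are kept, and true observations
    are computed from the noiseless labels.
    """
    rows, cols = scene_spec.image_size
    image = np.zeros((rows, cols))
    masks = []
    observations = []
    axis2d = None
    if len(truths) > 1:
        a0, _ = projection.project(truths[0].center)
        a1, _ = projection.project(truths[-1].center)
        axis2d = a1[0] - a0[0]
        axis2d /= np.linalg.norm(axis2d)
    marker_px_by_stent: dict[int, list] = {}
    for sid, p in markers_world:
        xy, ok = projection.project(p)
        if ok[0]:
            marker_px_by_stent.setdefault(sid, []).append(xy[0])

    wire = 0.125
    for i, tr in enumerate(truths):
        xy, ok = projection.project(tr.cloud)
        xy = xy[ok]
        ij = np.round(xy).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < cols) & (ij[:, 1] >= 0) & (ij[:, 1] < rows)
        if keep.sum() < len(ij):
            import warnings

            warnings.warn(f"stent {i} partially outside the field of view")
        ij = ij[keep]
        mask = np.zeros((rows, cols), bool)
        mask[ij[:, 1], ij[:, 0]] = True
        mag = projection.magnification(tr.center)
        w_px = max(1, int(round(wire * mag / 2.0 + 0.5)))
        mask = ndimage.binary_dilation(mask, structure=_disc(w_px))
        masks.append(mask)
        image[mask] = np.maximum(image[mask], 1.0)
        obs = make_observation(
            np.column_stack(np.nonzero(mask)[::-1]).astype(float),
            axis2d if axis2d is not None else np.array([0.0, 1.0]),
            stent_id=i,
            marker_points2d=np.array(marker_px_by_stent.get(i, [])).reshape(-1, 2),
        )
        observations.append(obs)

    # radiopaque markers: bright Gaussian dots
    yy, xx = np.mgrid[0:rows, 0:cols]
    for pts in marker_px_by_stent.values():
        for p in pts:
            image += 2.0 * np.exp(-(((xx - p[0]) ** 2 + (yy - p[1]) ** 2) / (2 * 1.2**2)))

    if scene_spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, scene_spec.blur_sigma)
    if scene_spec.noise > 0:
        image = image + scene_spec.noise * rng.standard_normal(image.shape)
    return image, masks, observations


# ----------------------------------------------------------------------
# Scene assembly + case I/O
# ----------------------------------------------------------------------


def build_scene(spec: SceneSpec, render: bool = True) -> SyntheticScene:
    graft = load_graft(spec.device) if isinstance(spec.device, str) else spec.device
    rng = np.random.default_rng(spec.seed)
    s0, sl = graft.stents[0], graft.stents[-1]
    z0 = s0.axial_position - s0.height / 2 - spec.margin
    z1 = sl.axial_position + sl.height / 2 + spec.margin
    vessel = make_vessel(spec, z0, z1)
    projection = ProjectionModel.c_arm(
        pixel_spacing=spec.pixel_spacing,
        image_size=spec.image_size,
        iso_center=(0.0, 0.0, 0.5 * (z0 + z1)),
        view_axis=(1.0, 0.0, 0.0),
        up=(0.0, 0.0, 1.0),
    )
    meshes = [build_zstent_mesh(s, spec.mesh_sizes) for s in graft.stents]
    centers, triads = device_path(spec, graft, z0, z1)
    if spec.phi_true is not None:
        phis = np.asarray(spec.phi_true, float)
    else:
        phis = rng.uniform(0.0, 2 * math.pi, graft.n_stents)
    truths = make_ground_truth(spec, graft, vessel, meshes, centers, triads, phis)

    fens_dev, markers_dev = place_fenestration_points(graft)
    fens_true = []
    for f in fens_dev:
        st = graft.stents[f.stent_index]
        tr = truths[f.stent_index]
        fens_true.append(
            FenestrationPoints(
                f.stent_index,
                stent_pose_transform(f.centroid, st, tr.center, tr.triad, tr.phi)[0],
                stent_pose_transform(f.rim, st, tr.center, tr.triad, tr.phi),
            )
        )
    markers_true = [
        (
            i,
            stent_pose_transform(
                p, graft.stents[i], truths[i].center, truths[i].triad, truths[i].phi
            )[0],
        )
        for i, p in markers_dev
    ]

    scene = SyntheticScene(
        spec=spec,
        graft=graft,
        vessel=vessel,
        projection=projection,
        stent_meshes=meshes,
        truths=truths,
        fenestrations_true=fens_true,
        markers_true=markers_true,
    )
    if render:
        scene.image, scene.masks, scene.observations = render_projection(
            spec, projection, truths, markers_true, rng
        )
    return scene


def preset_scene(name: str, seed: int = 0) -> SceneSpec:
    """Named study conditions: straight / curved / sac-phantom / fenestrated
    / patient-like aneurysm."""
    presets = {
        "straight": SceneSpec(
            device="synthetic_main_body_28_13", proximal_radius=12.0, distal_radius=10.0
        ),
        "curved": SceneSpec(
            device="synthetic_main_body_28_20",
            proximal_radius=12.0,
            distal_radius=10.5,
            bend_amplitude=8.0,
        ),
        "sac_phantom": SceneSpec(
            device="synthetic_main_body_28_13",
            proximal_radius=12.0,
            distal_radius=10.0,
            aneurysm_max_radius=27.0,
            sac_center=48.0,
            sac_length=60.0,
            sac_device_offset=2.5,
        ),
        "fenestrated": SceneSpec(
            device="synthetic_fenestrated_28", proximal_radius=12.5, distal_radius=10.5
        ),
        "patient_sac": SceneSpec(
            device="synthetic_main_body_28_20",
            proximal_radius=12.0,
            distal_radius=10.0,
            aneurysm_max_radius=20.0,
            sac_center=40.0,
            sac_length=50.0,
            bend_amplitude=4.0,
            sac_device_offset=1.5,
        ),
    }
    if name not in presets:
        raise SceneError(f"unknown preset '{name}' (have {sorted(presets)})")
    return replace(presets[name], seed=seed, name=name)


def write_case(scene: SyntheticScene, case_dir) -> None:
    """Write the fixed case-directory layout consumed by the pipeline."""
    import imageio.v3 as iio
    from pathlib import Path

    d = Path(case_dir)
    d.mkdir(parents=True, exist_ok=True)
    scene.vessel.save(d / "vessel.stl")
    np.savetxt(d / "centerline.txt", np.column_stack([scene.vessel.centerline, scene.vessel.radii]))
    save_graft(scene.graft, d / "device.yaml")
    scene.projection.save(d / "projection.json")
    if scene.image is not None:
        img = np.clip(scene.image / max(scene.image.max(), 1e-9), 0, 1)
        iio.imwrite(d / "target.png", (img * 65535).astype(np.uint16))
        stack = np.zeros(scene.image.shape, np.uint8)
        for i, m in enumerate(scene.masks):
            stack[m] = i + 1
        iio.imwrite(d / "masks.png", stack)
    save_observations(scene.observations, d / "observations.json")
    truth = {
        "stents": [
            {
                "center": t.center.tolist(),
                "triad": np.asarray(t.triad).tolist(),
                "phi": t.phi,
                "cloud": t.cloud.tolist(),
            }
            for t in scene.truths
        ],
        "fenestrations": [
            {
                "stent": f.stent_index,
                "centroid": f.centroid.tolist(),
                "rim": f.rim.tolist(),
            }
            for f in scene.fenestrations_true
        ],
        "markers": [[i, p.tolist()] for i, p in scene.markers_true],
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(truth, fh)
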