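"""C-arm projection model and target-image processing.

The mobile C-arm is a pinhole camera described by a calibrated 3x4 matrix P
mapping homogeneous world mm coordinates to homogeneous pixel coordinates.
Pixel convention: origin at the top-left, x = columns rightward, y = rows
downward.

The per-stent evidence extracted from a single X-ray target image is a
:class:`TargetObservation`: foreground pixel set, 2D convex hull, hull area
centroid (the 2D barycenter), apparent deployment diameters measured in the
proximal/distal end bands, and any radiopaque marker dots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage.feature import peak_local_max
from skimage.filters import frangi, threshold_otsu


class DegenerateHullError(ValueError):
    pass


class UnderSegmentationError(RuntimeError):
    def __init__(self, expected: int, found: int):
        super().__init__(f"expected {expected} stents, segmented {found}")
        self.expected = expected
        self.found = found


# ----------------------------------------------------------------------
# Projection model
# ----------------------------------------------------------------------


@dataclass
class ProjectionModel:
    """Calibrated 3x4 projection (world mm -> pixels)."""

    P: np.ndarray
    pixel_spacing: float = 1.0  # mm/px at the detector
    image_size: tuple[int, int] = (1024, 1024)  # (rows, cols)

    def __post_init__(self):
        self.P = np.asarray(self.P, float).reshape(3, 4)
        if np.linalg.matrix_rank(self.P[:, :3]) != 3:
            raise ValueError("left 3x3 block of P must have rank 3")

    @property
    def camera_center(self) -> np.ndarray:
        return -np.linalg.solve(self.P[:, :3], self.P[:, 3])

    @property
    def principal_axis(self) -> np.ndarray:
        M = self.P[:, :3]
        a = np.sign(np.linalg.det(M)) * M[2]
        return a / np.linalg.norm(a)

    def depth(self, pts3d: np.ndarray) -> np.ndarray:
        """Signed viewing depth (mm); positive in front of the source."""
        pts = np.atleast_2d(pts3d)
        w = pts @ self.P[2, :3] + self.P[2, 3]
        M = self.P[:, :3]
        return np.sign(np.linalg.det(M)) * w / np.linalg.norm(M[2])

    def project(self, pts3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates and a validity mask (False behind the source)."""
        pts = np.atleast_2d(np.asarray(pts3d, float))
        h = pts @ self.P[:, :3].T + self.P[:, 3]
        valid = self.depth(pts) > 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            xy = h[:, :2] / h[:, 2:3]
        return xy, valid

    def ray(self, pixel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-projection ray (origin = camera center, unit direction)."""
        x, y = np.asarray(pixel, float)
        d = np.linalg.solve(self.P[:, :3], np.array([x, y, 1.0]))
        d /= np.linalg.norm(d)
        if (d @ self.principal_axis) < 0:
            d = -d
        return self.camera_center, d

    def magnification(self, point3d: np.ndarray) -> float:
        """Local scale (px per mm) for in-plane offsets at a 3D point."""
        p = np.asarray(point3d, float)
        axis = self.principal_axis
        t = np.array([1.0, 0.0, 0.0])
        if abs(t @ axis) > 0.9:
            t = np.array([0.0, 1.0, 0.0])
        t = t - (t @ axis) * axis
        t /= np.linalg.norm(t)
        a, _ = self.project(np.vstack([p, p + t]))
        return float(np.linalg.norm(a[1] - a[0]))

    # -- constructors / IO -------------------------------------------
    @classmethod
    def c_arm(
        cls,
        source_to_detector: float = 1100.0,
        source_to_iso: float = 700.0,
        pixel_spacing: float = 0.3,
        image_size: tuple[int, int] = (1024, 1024),
        view_axis: np.ndarray = (1.0, 0.0, 0.0),
        up: np.ndarray = (0.0, 0.0, 1.0),
        iso_center: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "ProjectionModel":
        """Idealized C-arm geometry: source behind the isocenter on
        ``-view_axis``, detector plane beyond it, image y along ``-up``."""
        z = np.asarray(view_axis, float)
        z = z / np.linalg.norm(z)
        u = np.asarray(up, float)
        u = u - (u @ z) * z
        u /= np.linalg.norm(u)
        x = np.cross(-u, z)
        R = np.vstack([x, -u, z])  # world -> camera
        C = np.asarray(iso_center, float) - source_to_iso * z
        f = source_to_detector / pixel_spacing
        Kc = np.array(
            [
                [f, 0.0, image_size[1] / 2.0],
                [0.0, f, image_size[0] / 2.0],
                [0.0, 0.0, 1.0],
            ]
        )
        P = Kc @ np.hstack([R, -R @ C[:, None]])
        return cls(P=P, pixel_spacing=pixel_spacing, image_size=tuple(image_size))

    def to_dict(self) -> dict:
        return {
            "P": self.P.tolist(),
            "pixel_spacing": self.pixel_spacing,
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            P=np.asarray(d["P"], float),
            pixel_spacing=float(d.get("pixel_spacing", 1.0)),
            image_size=tuple(d.get("image_size", (1024, 1024))),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def project_points(P: ProjectionModel, pts3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard homogeneous projection with perspective divide.

    Points behind the source plane are flagged invalid and must be excluded
    from downstream distances.
    """
    return P.project(pts3d)


# ----------------------------------------------------------------------
# Target observations
# ----------------------------------------------------------------------


@dataclass
class TargetObservation:
    """Per-stent 2D evidence extracted from the X-ray target image."""

    stent_id: int
    hull2d: np.ndarray  # (V, 2) convex polygon, pixel coordinates
    barycenter2d: np.ndarray  # (2,)
    apparent_diam_proximal: float  # px
    apparent_diam_distal: float  # px
    marker_points2d: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    pixel_set: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def to_dict(self) -> dict:
        return {
            "stent_id": self.stent_id,
            "hull2d": np.asarray(self.hull2d).tolist(),
            "barycenter2d": np.asarray(self.barycenter2d).tolist(),
            "apparent_diam_proximal": self.apparent_diam_proximal,
            "apparent_diam_distal": self.apparent_diam_distal,
            "marker_points2d": np.asarray(self.marker_points2d).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetObservation":
        return cls(
            stent_id=int(d["stent_id"]),
            hull2d=np.asarray(d["hull2d"], float),
            barycenter2d=np.asarray(d["barycenter2d"], float),
            apparent_diam_proximal=float(d["apparent_diam_proximal"]),
            apparent_diam_distal=float(d["apparent_diam_distal"]),
            marker_points2d=np.asarray(d.get("marker_points2d", []), float).reshape(-1, 2),
            pixel_set=np.asarray(d.get("pixel_set", []), float).reshape(-1, 2),
        )


def save_observations(obs: list[TargetObservation], path) -> None:
    with open(path, "w") as fh:
        json.dump([o.to_dict() for o in obs], fh)


def load_observations(path) -> list[TargetObservation]:
    with open(path) as fh:
        return [TargetObservation.from_dict(d) for d in json.load(fh)]


def make_observation(
    pixels: np.ndarray,
    device_axis_2d: np.ndarray,
    stent_id: int = 0,
    marker_points2d: np.ndarray | None = None,
    band_fraction: float = 0.2,
) -> TargetObservation:
    """Observation from a per-stent foreground pixel set.

    The 2D barycenter is the *area centroid* of the convex-hull polygon
    (robust to pixel density). Apparent deployment diameters are the pixel
    extents perpendicular to the device axis, measured inside the
    proximal-most and distal-most ``band_fraction`` axial bands; the axis
    must point proximal -> distal.
    """
    px = np.asarray(pixels, float).reshape(-1, 2)
    if len(px) < 3:
        raise DegenerateHullError("need at least 3 pixels")
    hull = MultiPoint(px).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateHullError("pixel set is collinear")
    ring = np.asarray(hull.exterior.coords)[:-1]
    bary = np.array(hull.centroid.coords[0])

    axis = np.asarray(device_axis_2d, float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    t = px @ axis
    s = px @ perp
    t0, t1 = t.min(), t.max()
    band = band_fraction * (t1 - t0)

    def width(mask):
        if not np.any(mask):
            return 0.0
        # +1: pixel footprint extent, not center-to-center distance
        return float(s[mask].max() - s[mask].min() + 1.0)

    return TargetObservation(
        stent_id=stent_id,
        hull2d=ring,
        barycenter2d=bary,
        apparent_diam_proximal=width(t <= t0 + band),
        apparent_diam_distal=width(t >= t1 - band),
        marker_points2d=(
            np.zeros((0, 2)) if marker_points2d is None else np.asarray(marker_points2d, float)
        ),
        pixel_set=px,
    )


# ----------------------------------------------------------------------
# Segmentation of the target image
# ----------------------------------------------------------------------


def extract_stent_pixels(
    image: np.ndarray,
    n_stents_expected: int,
    masks: list[np.ndarray] | None = None,
    polarity: str = "bright",
    scales=(1, 2, 3, 4),
    device_axis_2d: np.ndarray | None = None,
    dilate: int = 3,
    intensity_floor: float = 0.1,
    min_component_size: int = 20,
) -> list[np.ndarray]:
    """Per-stent foreground pixel sets, ordered proximal -> distal.

    A Frangi vesselness response (wire-like structures) is thresholded at
    Otsu's level; connected components are grouped into stents by their
    ordering along the device direction. Synthetic or user masks, when
    given, take precedence and split touching stents exactly.
    """
    img = np.asarray(image, float)
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    if polarity == "dark":
        img = 1.0 - img

    if masks is not None:
        if len(masks) != n_stents_expected:
            raise UnderSegmentationError(n_stents_expected, len(masks))
        out = []
        for m in masks:
            yy, xx = np.nonzero(np.asarray(m))
            out.append(np.column_stack([xx, yy]).astype(float))
        return out

    resp = frangi(img, sigmas=scales, black_ridges=False)
    if resp.max() <= 0:
        raise UnderSegmentationError(n_stents_expected, 0)
    fg = resp > threshold_otsu(resp)
    lab0, n0 = ndimage.label(fg)
    if n0 and min_component_size > 1:
        sizes = ndimage.sum(fg, lab0, range(1, n0 + 1))
        fg = np.isin(lab0, np.where(sizes >= min_component_size)[0] + 1)
    if dilate > 0:
        # the vesselness ridge peaks on the wire centerline; grow back to
        # the full strut width, then keep only plausibly bright pixels
        fg = ndimage.binary_dilation(fg, iterations=dilate) & (img > intensity_floor)
    labels, n_comp = ndimage.label(fg)
    if n_comp == 0:
        raise UnderSegmentationError(n_stents_expected, 0)

    yy, xx = np.nonzero(fg)
    pts = np.column_stack([xx, yy]).astype(float)
    if device_axis_2d is None:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    else:
        axis = np.asarray(device_axis_2d, float)
    axis = axis / np.linalg.norm(axis)

    comp_pts = [
        np.column_stack(np.nonzero(labels == k)[::-1]).astype(float)
        for k in range(1, n_comp + 1)
    ]
    intervals = []
    for cp in comp_pts:
        tc = cp @ axis
        intervals.append([tc.min(), tc.max()])
    order = np.argsort([0.5 * (a + b) for a, b in intervals])
    groups: list[list[int]] = []
    for idx in order:
        a, b = intervals[idx]
        if groups and a <= max(intervals[g][1] for g in groups[-1]):
            groups[-1].append(idx)
        else:
            groups.append([idx])
    while len(groups) > n_stents_expected:
        gaps = [
            min(intervals[j][0] for j in groups[k + 1])
            - max(intervals[j][1] for j in groups[k])
            for k in range(len(groups) - 1)
        ]
        k = int(np.argmin(gaps))
        groups[k] = groups[k] + groups.pop(k + 1)
    if len(groups) < n_stents_expected:
        raise UnderSegmentationError(n_stents_expected, len(groups))
    return [np.vstack([comp_pts[i] for i in g]) for g in groups]


def detect_markers(
    image: np.ndarray,
    pixel_set: np.ndarray,
    percentile: float = 99.0,
    min_distance: int = 2,
    mask_dilation: int = 6,
) -> np.ndarray:
    """Radiopaque marker dots: local intensity maxima inside the stent mask
    above the given intensity percentile. Returns (K, 2) pixel (x, y)."""
    img = np.asarray(image, float)
    mask = np.zeros(img.shape, bool)
    ij = np.round(np.asarray(pixel_set, float)).astype(int)
    ij = ij[
        (ij[:, 0] >= 0) & (ij[:, 0] < img.shape[1]) & (ij[:, 1] >= 0) & (ij[:, 1] < img.shape[0])
    ]
    mask[ij[:, 1], ij[:, 0]] = True
    # markers can sit in strut-free interior regions of the silhouette
    mask = ndimage.binary_dilation(mask, iterations=mask_dilation)
    vals = img[mask]
    if vals.size == 0:
        return np.zeros((0, 2))
    thr = np.percentile(vals, percentile)
    peaks = peak_local_max(
        np.where(mask, img, 0.0), min_distance=min_distance, threshold_abs=thr
    )
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


# ----------------------------------------------------------------------
# Back-projection polyhedron
# ----------------------------------------------------------------------


def back_project_hull(
    P: ProjectionModel, hull2d: np.ndarray, depth_range: tuple[float, float]
) -> trimesh.Trimesh:
    """Truncated-cone polyhedron of all points projecting inside a 2D hull.

    Hull vertices are back-projected to rays from the source and clipped
    between the near and far viewing-depth planes; the result is a
    watertight, outward-oriented triangulated prism.
    """
    near, far = depth_range
    if not 0 < near < far:
        raise ValueError("need 0 < near < far")
    hull = np.asarray(hull2d, float).reshape(-1, 2)
    if len(hull) < 3:
        raise DegenerateHullError("hull needs at least 3 vertices")
    C = P.camera_center
    axis = P.principal_axis
    dirs = []
    for v in hull:
        _, d = P.ray(v)
        dirs.append(d / (d @ axis))  # unit depth parameterization
    dirs = np.array(dirs)
    ring_near = C + near * dirs
    ring_far = C + far * dirs
    n = len(hull)
    verts = np.vstack([ring_near, ring_far])
    faces = []
    for k in range(n):
        k2 = (k + 1) % n
        faces.append([k, k2, n + k2])
        faces.append([k, n + k2, n + k])
    for k in range(1, n - 1):  # caps (convex fan)
        faces.append([0, k + 1, k])
        faces.append([n, n + k, n + k + 1])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh
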