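"""Projection model and target-image processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmvsd.imaging import (
    DegenerateHullError,
    ProjectionModel,
    TargetObservation,
    UnderSegmentationError,
    back_project_hull,
    extract_stent_pixels,
    make_observation,
    project_points,
)


@pytest.fixture(scope="module")
def carm():
    return ProjectionModel.c_arm()


class TestProjection:
    def test_pinhole_normalized_units(self):
        """Canonical P = [I|0]: (2, 3, 10) projects to (0.2, 0.3)."""
        P = ProjectionModel(np.hstack([np.eye(3), np.zeros((3, 1))]))
        xy, ok = project_points(P, [[2.0, 3.0, 10.0]])
        assert ok[0]
        assert np.allclose(xy[0], [0.2, 0.3])

    def test_behind_source_flagged(self):
        P = ProjectionModel(np.hstack([np.eye(3), np.zeros((3, 1))]))
        _, ok = project_points(P, [[0.0, 0.0, -5.0]])
        assert not ok[0]

    def test_backprojection_ray_roundtrip(self, carm):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-40, 40, size=(20, 3))
        xy, ok = carm.project(pts)
        assert ok.all()
        for p, q in zip(pts, xy):
            o, d = carm.ray(q)
            t = (p - o) @ d
            assert np.linalg.norm(o + t * d - p) < 1e-9

    def test_dlt_recovers_projections(self, carm):
        """Recomputing P by direct linear transform from correspondences
        reproduces every projection to < 1e-6 px."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(-50, 50, size=(12, 3))
        xy, _ = carm.project(pts)
        A = []
        for (X, Y, Z), (u, v) in zip(pts, xy):
            A.append([X, Y, Z, 1, 0, 0, 0, 0, -u * X, -u * Y, -u * Z, -u])
            A.append([0, 0, 0, 0, X, Y, Z, 1, -v * X, -v * Y, -v * Z, -v])
        _, _, vt = np.linalg.svd(np.asarray(A))
        P_dlt = ProjectionModel(vt[-1].reshape(3, 4))
        xy2, _ = P_dlt.project(pts)
        assert np.abs(xy2 - xy).max() < 1e-6

    def test_rank_deficient_P_rejected(self):
        P = np.zeros((3, 4))
        P[0, 0] = P[1, 1] = 1.0
        with pytest.raises(ValueError):
            ProjectionModel(P)

    def test_magnification_matches_geometry(self, carm):
        # f/z at the isocenter: (SDD / pixel) / SID
        assert carm.magnification([0.0, 0.0, 0.0]) == pytest.approx(
            (1100.0 / 0.3) / 700.0, rel=1e-6
        )


class TestObservation:
    def test_rectangle_diameters(self):
        xs, ys = np.meshgrid(np.arange(40), np.arange(80))
        px = np.column_stack([xs.ravel(), ys.ravel()])
        obs = make_observation(px, device_axis_2d=[0.0, 1.0])
        assert obs.apparent_diam_proximal == pytest.approx(40.0)
        assert obs.apparent_diam_distal == pytest.approx(40.0)
        assert np.allclose(obs.barycenter2d, [19.5, 39.5], atol=0.5)

    def test_disc_barycenter(self):
        yy, xx = np.mgrid[0:240, 0:240]
        mask = (xx - 100) ** 2 + (yy - 120) ** 2 <= 50**2
        px = np.column_stack([xx[mask], yy[mask]])
        obs = make_observation(px, [0.0, 1.0])
        assert np.allclose(obs.barycenter2d, [100.0, 120.0], atol=0.5)

    def test_hull_contains_pixels_and_barycenter(self):
        rng = np.random.default_rng(2)
        px = rng.uniform(0, 100, size=(200, 2))
        obs = make_observation(px, [1.0, 0.0])
        from shapely.geometry import Point, Polygon

        poly = Polygon(obs.hull2d).buffer(1e-9)
        assert poly.contains(Point(obs.barycenter2d))
        assert all(poly.contains(Point(p)) for p in px)

    def test_collinear_pixels_rejected(self):
        px = np.column_stack([np.arange(10), np.arange(10)])
        with pytest.raises(DegenerateHullError):
            make_observation(px, [0.0, 1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        dx=st.integers(min_value=-300, max_value=300),
        dy=st.integers(min_value=-300, max_value=300),
    )
    def test_translation_equivariance(self, dx, dy):
        """Shifting the pixel set shifts the barycenter exactly and leaves
        the apparent diameters unchanged."""
        rng = np.random.default_rng(42)
        px = rng.uniform(0, 60, size=(150, 2))
        a = make_observation(px, [0.0, 1.0])
        b = make_observation(px + [dx, dy], [0.0, 1.0])
        assert np.allclose(b.barycenter2d - a.barycenter2d, [dx, dy], atol=1e-9)
        assert b.apparent_diam_proximal == pytest.approx(a.apparent_diam_proximal)
        assert b.apparent_diam_distal == pytest.approx(a.apparent_diam_distal)

    def test_json_roundtrip(self, tmp_path):
        from fmvsd.imaging import load_observations, save_observations

        px = np.array([[0, 0], [10, 0], [0, 10], [10, 10.0]])
        obs = make_observation(px, [0.0, 1.0], stent_id=3)
        path = tmp_path / "obs.json"
        save_observations([obs], path)
        loaded = load_observations(path)[0]
        assert loaded.stent_id == 3
        assert np.allclose(loaded.barycenter2d, obs.barycenter2d)


class TestSegmentation:
    def _render_rings(self, centers, radius=30, size=256):
        img = np.zeros((size, size))
        yy, xx = np.mgrid[0:size, 0:size]
        labels = []
        for cx, cy in centers:
            ring = np.abs(np.hypot(xx - cx, yy - cy) - radius) < 2
            img[ring] = 1.0
            labels.append(ring)
        return img, labels

    def test_single_ring_recall(self):
        img, labels = self._render_rings([(128, 128)])
        sets = extract_stent_pixels(img, 1)
        got = {tuple(p) for p in np.round(sets[0]).astype(int)}
        truth = {tuple(p) for p in np.column_stack(np.nonzero(labels[0])[::-1])}
        recall = len(got & truth) / len(truth)
        assert recall >= 0.99

    def test_blank_image_errors(self):
        with pytest.raises(UnderSegmentationError):
            extract_stent_pixels(np.zeros((64, 64)), 1)

    def test_multiple_rings_axial_order(self):
        centers = [(60, 40 + 85 * k) for k in range(3)]
        img, labels = self._render_rings(centers, radius=25, size=300)
        sets = extract_stent_pixels(img, 3, device_axis_2d=[0.0, 1.0])
        assert len(sets) == 3
        means = [s[:, 1].mean() for s in sets]
        assert means == sorted(means)

    def test_masks_take_precedence(self):
        img, labels = self._render_rings([(128, 128)])
        sets = extract_stent_pixels(img, 1, masks=labels)
        assert len(sets[0]) == labels[0].sum()


class TestBackProjection:
    def test_prism_volume_matches_frustum(self, carm):
        hull = np.array([[400, 400], [600, 400], [600, 600], [400, 600.0]])
        near, far = 650.0, 750.0
        m = back_project_hull(carm, hull, (near, far))
        assert m.is_watertight
        f = 1100.0 / 0.3
        side = 200.0 / f  # px -> mm per unit depth
        exact = (far**3 - near**3) / 3.0 * side**2
        assert m.volume == pytest.approx(exact, rel=0.01)

    def test_containment_oracle(self, carm):
        """Every 3D point projecting inside the hull within the depth range
        lies inside the polyhedron."""
        from fmvsd._meshgeom import mesh_contains
        from shapely.geometry import Point, Polygon

        hull = np.array([[450, 430], [620, 470], [580, 620], [460, 580.0]])
        near, far = 660.0, 740.0
        m = back_project_hull(carm, hull, (near, far))
        rng = np.random.default_rng(3)
        pts = rng.uniform([-40, -40, -40], [40, 40, 40], size=(1000, 3))
        xy, _ = carm.project(pts)
        depth = carm.depth(pts)
        poly = Polygon(hull)
        margin = 1.0  # off-surface margin for the voxel-free exact check
        expect_in = np.array(
            [
                poly.buffer(-2).contains(Point(q)) and near + margin < d < far - margin
                for q, d in zip(xy, depth)
            ]
        )
        inside = mesh_contains(m, pts)
        assert np.all(inside[expect_in])
        expect_out = np.array(
            [not poly.buffer(2).contains(Point(q)) or not (near - margin < d < far + margin)
             for q, d in zip(xy, depth)]
        )
        assert not np.any(inside & expect_out)

    def test_thin_slab_depths(self, carm):
        hull = np.array([[480, 480], [540, 480], [510, 560.0]])
        m = back_project_hull(carm, hull, (100.0, 101.0))
        d = carm.depth(m.vertices)
        assert d.min() >= 100.0 - 1e-9
        assert d.max() <= 101.0 + 1e-9

    def test_degenerate_hull_rejected(self, carm):
        with pytest.raises(DegenerateHullError):
            back_project_hull(carm, np.array([[0, 0], [1, 1.0]]), (10, 20))
        with pytest.raises(ValueError):
            back_project_hull(
                carm, np.array([[0, 0], [10, 0], [0, 10.0]]), (50.0, 40.0)
            )
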