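"""Parametric device construction: Z-stent meshes, centerline model,
fenestrations and markers."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fmvsd.devices import (
    CENTERLINE_E,
    CENTERLINE_NU,
    Fenestration,
    GraftSpec,
    InvalidSpecError,
    StentSpec,
    auto_markers,
    build_centerline_assembly,
    build_zstent_mesh,
    graft_from_dict,
    graft_to_dict,
    load_graft,
    place_fenestration_points,
    stent_pose_transform,
)
from fmvsd.fem import SolverParams, solve_equilibrium


@pytest.fixture(scope="module")
def stent28():
    return StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)


@pytest.fixture(scope="module")
def mesh28(stent28):
    return build_zstent_mesh(stent28, (2.0, 0.1))


class TestZStentMesh:
    def test_limb_and_apex_counts(self, mesh28):
        assert mesh28.limb_count == 10  # 2 * n_peaks
        assert mesh28.apex_count == 10

    def test_five_fold_symmetry(self, mesh28):
        th = 2 * math.pi / 5
        R = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1.0]]
        )
        rotated = mesh28.cloud @ R.T
        d, _ = cKDTree(mesh28.cloud).query(rotated)
        assert d.max() < 1e-6

    def test_nominal_radius_band(self, mesh28, stent28):
        r = np.linalg.norm(mesh28.cloud[:, :2], axis=1)
        assert r.max() <= 14.0 + stent28.wire_diameter
        assert r.max() >= 14.0 - stent28.wire_diameter

    def test_mesh_size_bounds(self, mesh28):
        lengths = np.array([e.l0 for e in mesh28.assembly.elements])
        tags = np.array(mesh28.element_tags)
        assert lengths[tags == "apex"].max() <= 0.1 * 1.05
        assert lengths[tags == "limb"].max() <= 2.0 * 1.05

    def test_cloud_density_and_barycenter(self, mesh28):
        # consecutive cloud points <= fine mesh size apart along the wire
        gaps = np.linalg.norm(np.diff(mesh28.cloud, axis=0), axis=1)
        assert gaps.max() <= 0.1 + 1e-9
        assert np.allclose(mesh28.V.mean(axis=0), 0.0, atol=1e-9)

    def test_taper_interpolates_diameters(self):
        s = StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=14.0)
        m = build_zstent_mesh(s, (2.0, 0.2))
        r = np.linalg.norm(m.cloud[:, :2], axis=1)
        z = m.cloud[:, 2]
        proximal = r[z < -6.0]  # device z runs proximal -> distal
        distal = r[z > 6.0]
        assert abs(proximal.mean() - 14.0) < 1.0
        assert abs(distal.mean() - 7.0) < 1.0

    def test_rebuild_is_bit_identical(self, stent28, mesh28):
        again = build_zstent_mesh(stent28, (2.0, 0.1))
        assert np.array_equal(again.cloud, mesh28.cloud)
        assert np.array_equal(again.assembly.positions(), mesh28.assembly.positions())

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_zstent_mesh(
                StentSpec(n_peaks=24, height=2.0, diameter_proximal=8.0, diameter_distal=8.0,
                          wire_diameter=0.5),
                (2.0, 0.1),
            )
        with pytest.raises(InvalidSpecError):
            build_zstent_mesh(
                StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0),
                (0.1, 2.0),  # coarse < fine
            )


class TestCenterlineModel:
    def test_counts_and_materials(self):
        g = load_graft("synthetic_main_body_28_13")
        a = build_centerline_assembly(g)
        assert len(a.elements) == 7
        assert len(a.joints) == 6
        for e in a.elements:
            assert e.section.E == CENTERLINE_E
            assert e.section.nu == CENTERLINE_NU

    def test_empty_graft_rejected(self):
        with pytest.raises(InvalidSpecError):
            GraftSpec(stents=[])

    def test_bent_chain_stays_bent(self, mini_graft):
        """Joints transmit force but no moment: a kinked chain is already in
        equilibrium with zero residual moment at the joint."""
        a = build_centerline_assembly(mini_graft)
        # rotate the last beam 90 degrees about the joint
        e = a.elements[-1]
        na, nb = e.nodes
        pivot = a.nodes[na].position.copy()
        a.nodes[nb].position = pivot + np.array([e.l0, 0.0, 0.0])
        a.nodes[na].rotation = np.array([0.0, np.pi / 2, 0.0])
        a.nodes[nb].rotation = np.array([0.0, np.pi / 2, 0.0])
        res = solve_equilibrium(a, params=SolverParams(tol_force=1e-6, max_steps=20000))
        assert res.converged
        d = res.positions[nb] - res.positions[na]
        assert abs(d[0]) == pytest.approx(e.l0, abs=1e-6)  # still perpendicular


class TestFenestrations:
    def test_centroid_on_surface(self):
        stents = [StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0,
                            diameter_distal=28.0, axial_position=5.0)]
        fens = [Fenestration(0, 0.0, 0.0, 3.0)]
        g = GraftSpec(stents=stents, fenestrations=fens, markers=auto_markers(stents, fens))
        placed, markers = place_fenestration_points(g)
        assert np.allclose(placed[0].centroid, [14.0, 0.0, 5.0])
        assert np.allclose(placed[0].rim.mean(axis=0), placed[0].centroid, atol=1e-9)
        assert len(markers) == 2

    def test_angular_separation(self):
        stents = [StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)]
        fens = [Fenestration(0, 0.0, 0.0, 2.0), Fenestration(0, math.pi / 2, 0.0, 2.0)]
        g = GraftSpec(stents=stents, fenestrations=fens, markers=auto_markers(stents, fens))
        placed, _ = place_fenestration_points(g)
        a = placed[0].centroid[:2]
        b = placed[1].centroid[:2]
        ang = math.acos(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert ang == pytest.approx(math.pi / 2, abs=1e-6)

    def test_rotation_carries_fenestration(self):
        """Rotating the host stent by 40 degrees rotates the fenestration
        centroid by exactly 40 degrees about the stent axis."""
        stents = [StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)]
        fens = [Fenestration(0, 0.3, 1.0, 2.0)]
        g = GraftSpec(stents=stents, fenestrations=fens, markers=auto_markers(stents, fens))
        placed, _ = place_fenestration_points(g)
        phi = math.radians(40.0)
        moved = stent_pose_transform(placed[0].centroid, stents[0], np.zeros(3), np.eye(3), phi)[0]
        c, s = math.cos(phi), math.sin(phi)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        assert np.allclose(moved, R @ placed[0].centroid, atol=1e-12)

    def test_fenestrated_stent_requires_marker(self):
        stents = [StentSpec(n_peaks=5, height=14.0, diameter_proximal=28.0, diameter_distal=28.0)]
        with pytest.raises(InvalidSpecError):
            GraftSpec(stents=stents, fenestrations=[Fenestration(0, 0.0, 0.0, 2.0)], markers=[])

    def test_oversized_fenestration_rejected(self):
        stents = [StentSpec(n_peaks=5, height=10.0, diameter_proximal=28.0, diameter_distal=28.0)]
        fen = [Fenestration(0, 0.0, 0.0, 12.0)]
        with pytest.raises(InvalidSpecError):
            GraftSpec(stents=stents, fenestrations=fen, markers=auto_markers(stents, fen))


class TestGraftIO:
    def test_yaml_roundtrip(self, mini_graft, tmp_path):
        d = graft_to_dict(mini_graft)
        g2 = graft_from_dict(d)
        assert g2.n_stents == mini_graft.n_stents
        assert g2.stents == mini_graft.stents
        assert len(g2.markers) == len(mini_graft.markers)

    @pytest.mark.parametrize(
        "name", ["synthetic_main_body_28_13", "synthetic_main_body_28_20", "synthetic_fenestrated_28"]
    )
    def test_bundled_fixtures_load(self, name):
        g = load_graft(name)
        assert g.stents[0].diameter_proximal == 28.0
        assert 5 <= g.n_stents <= 7
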