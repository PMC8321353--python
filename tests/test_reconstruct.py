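"""Combining camera views into the reconstructable subset."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from reconsim import geometry2d as g2
from reconsim.camera import make_ring_setup
from reconsim.mesh_io import validate_mesh, write_binary_stl
from reconsim.reconstruct import (
    ReconConfig,
    area_summary,
    camera_lists,
    combo_count,
    reconstructable_face,
    reconstructable_subset,
)
from reconsim.visibility import FaceFragments, visible_subset

SETUP4 = make_ring_setup(4, 30, 400)

FRAME = g2.local_frame([(0, 0, 0), (10, 0, 0), (0, 10, 0)])
FACE = Polygon([(0, 0), (10, 0), (0, 10)])


def frag(polygon, full=False):
    return FaceFragments(index=0, frame=FRAME, polygon=polygon, tag="", full=full)


class TestCameraLists:
    def test_plate_seen_by_all_four(self, plate):
        maps = [visible_subset(plate, c) for c in SETUP4.cameras]
        lists = camera_lists(maps)
        assert lists == {0: [0, 1, 2, 3], 1: [0, 1, 2, 3]}

    def test_invisible_face_absent(self, plate):
        from test_visibility import flipped

        maps = [visible_subset(flipped(plate), c) for c in SETUP4.cameras]
        assert camera_lists(maps) == {}


class TestComboCount:
    @pytest.mark.parametrize("n,t,expected", [(4, 2, 6), (2, 2, 1), (1, 2, 0), (0, 0, 1)])
    def test_binomial_values(self, n, t, expected):
        assert combo_count(n, t) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            combo_count(-1, 2)


class TestReconstructableFace:
    def test_two_full_views_reconstruct_whole_face(self):
        out = reconstructable_face(FACE, [frag(FACE, True), frag(FACE, True)], T=2)
        assert out.area == pytest.approx(FACE.area)

    def test_disjoint_halves_reconstruct_nothing(self):
        left = shapely.intersection(FACE, box(-1, -1, 3, 11))
        right = shapely.intersection(FACE, box(3, -1, 11, 11))
        out = reconstructable_face(FACE, [frag(left), frag(right)], T=2)
        assert out.is_empty

    def test_below_threshold_is_empty(self):
        assert reconstructable_face(FACE, [frag(FACE, True)], T=2).is_empty

    def test_enumerate_cap_refuses(self):
        piece = shapely.intersection(FACE, box(0, 0, 8, 8))
        frags = [frag(piece)] * 30
        with pytest.raises(ValueError, match="coverage_count"):
            reconstructable_face(FACE, frags, T=2, strategy="enumerate", enumerate_cap=10)

    @pytest.mark.parametrize("T", [2, 3])
    def test_strategies_and_point_sampling_agree(self, T):
        """enumerate == coverage_count == Monte-Carlo membership count on
        random fragment constellations with up to 6 cameras."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = rng.integers(T, 7)
            frags = []
            for _j in range(m):
                clip = box(*np.sort(rng.uniform(-2, 12, 2)), *np.sort(rng.uniform(-2, 12, 2)))
                piece = shapely.intersection(FACE, clip)
                frags.append(frag(piece))
            enum = reconstructable_face(FACE, frags, T, strategy="enumerate")
            cov = reconstructable_face(FACE, frags, T, strategy="coverage_count")
            assert cov.area == pytest.approx(enum.area, rel=1e-7, abs=1e-9)

            n = 4000
            r1 = np.sqrt(rng.uniform(size=n))
            r2 = rng.uniform(size=n)
            pts = np.column_stack(
                [10 * r1 * (1 - r2), 10 * r1 * r2]
            )  # uniform in the triangle
            pts_geom = shapely.points(pts)
            counts = np.zeros(n)
            for f in frags:
                counts += shapely.contains(f.polygon, pts_geom)
            p = (counts >= T).mean()
            se = max(np.sqrt(p * (1 - p) / n), 1e-9)
            assert cov.area / FACE.area == pytest.approx(p, abs=3 * se + 1e-9)


class TestReconstructableSubset:
    @pytest.mark.parametrize("M", [2, 4, 8])
    def test_unoccluded_plate_fully_reconstructable(self, plate, M):
        setup = make_ring_setup(M, 30, 400)
        res = reconstructable_subset(plate, setup)
        assert res.area == pytest.approx(400.0, rel=1e-9)

    def test_opposite_cameras_reconstruct_no_wall(self, empty_channel):
        """With two opposite cameras each wall azimuth is front-facing to at
        most one of them, so no wall region reaches the T=2 threshold."""
        res = reconstructable_subset(empty_channel, make_ring_setup(2, 30, 400))
        assert res.area_by_tag.get("wall", 0.0) == pytest.approx(0.0, abs=1e-6)
        assert res.area_by_tag["anatomy"] > 0.0

    def test_adding_a_camera_never_decreases_area(self, empty_channel):
        base = make_ring_setup(8, 30, 400)
        areas = []
        for k in (2, 3, 4, 5):
            sub = base.subset(range(k))
            areas.append(reconstructable_subset(empty_channel, sub).area)
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_higher_threshold_never_increases_area(self, empty_channel):
        setup = make_ring_setup(4, 30, 400)
        maps = [visible_subset(empty_channel, c) for c in setup.cameras]
        a2 = reconstructable_subset(empty_channel, setup, ReconConfig(T=2), maps).area
        a3 = reconstructable_subset(empty_channel, setup, ReconConfig(T=3), maps).area
        assert a3 <= a2 + 1e-9

    def test_fragments_contained_in_parent_faces(self, stacked_plates):
        res = reconstructable_subset(stacked_plates, SETUP4)
        areas = stacked_plates.face_areas()
        rng = np.random.default_rng(1)
        cache_tri = stacked_plates.triangles()
        for i, f in res.fragments.items():
            assert f.area <= areas[i] + 1e-8
            # point-sample the fragment: every point lies in the parent face
            tri2 = g2.to_local(f.frame, cache_tri[i])
            parent = Polygon(tri2)
            minx, miny, maxx, maxy = f.polygon.bounds
            pts = rng.uniform((minx, miny), (maxx, maxy), size=(200, 2))
            inside = shapely.contains(f.polygon, shapely.points(pts))
            assert shapely.contains(parent.buffer(1e-9), shapely.points(pts[inside])).all()

    def test_export_is_fragment_soup_with_matching_area(self, tmp_path, stacked_plates):
        res = reconstructable_subset(stacked_plates, SETUP4)
        out = res.to_mesh()
        assert out.total_area() == pytest.approx(res.area, rel=1e-9)
        path = tmp_path / "recon.stl"
        write_binary_stl(out, path)
        assert not validate_mesh(out).watertight  # open fragment borders


class TestAreaSummary:
    def test_benchmark_row_is_one(self, plate):
        results = {
            M: reconstructable_subset(plate, make_ring_setup(M, 30, 400))
            for M in (2, 4)
        }
        df = area_summary(results, benchmark_M=4)
        assert df.loc[df["n"] == 4, "norm"].item() == pytest.approx(1.0)

    def test_exclude_top_without_tags_is_identity(self, plate):
        results = {
            M: reconstructable_subset(plate, make_ring_setup(M, 30, 400))
            for M in (2, 4)
        }
        incl = area_summary(results, benchmark_M=4)
        excl = area_summary(results, benchmark_M=4, exclude_top=True)
        assert np.allclose(incl["norm"], excl["norm"])

    def test_exclude_top_drops_top_surface_share(self, empty_channel):
        results = {
            M: reconstructable_subset(empty_channel, make_ring_setup(M, 30, 400))
            for M in (2, 4)
        }
        excl = area_summary(results, benchmark_M=4, exclude_top=True)
        incl = area_summary(results, benchmark_M=4)
        top4 = results[4].area_by_tag["top_surface"]
        assert excl.loc[1, "Ar_mm2"] == pytest.approx(incl.loc[1, "Ar_mm2"] - top4)
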