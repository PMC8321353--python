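"""Per-camera visibility: culling, occluders, clipping, analytic oracles."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from reconsim.camera import make_ring_setup, project_point
from reconsim.mesh_io import TriangleMesh
from reconsim.visibility import (
    clip_to_fov,
    cull_faces,
    find_occluders,
    visible_subset,
)

from conftest import square_plate

SETUP4 = make_ring_setup(4, 30, 400)
CAM = SETUP4.cameras[0]


def flipped(mesh: TriangleMesh) -> TriangleMesh:
    return TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[:, ::-1])


class TestCulling:
    def test_upward_plate_is_kept_inside_fov(self, plate):
        cands = cull_faces(plate, CAM)
        assert {c.index for c in cands} == {0, 1}
        assert all(c.fov_status == "inside" for c in cands)

    def test_downward_plate_is_culled(self, plate):
        assert cull_faces(flipped(plate), CAM) == []

    def test_contour_face_with_perpendicular_normal_is_culled(self):
        # fin normal +x; a camera with aperture x = 0 exactly views it
        # edge-on (dot = 0 -> contour)
        from reconsim.camera import make_camera

        cam = make_camera((0.0, 15.0, 400.0))
        fin = TriangleMesh(
            vertices=[(0, -1, 0), (0, 1, 0), (0, 0, 5)], faces=[[0, 1, 2]]
        )
        assert fin.normals[0] @ cam.view_dir == 0.0
        assert cull_faces(fin, cam) == []

    def test_face_outside_fov_is_culled(self):
        far = square_plate(half=2.0)
        far.vertices = far.vertices + np.array([100.0, 0.0, 0.0])
        assert cull_faces(far, CAM) == []

    def test_straddling_face_is_flagged(self):
        # 18 mm half-width FOV edge at x ~ +-18 in the focal plane
        wide = square_plate(half=25.0)
        cands = cull_faces(wide, CAM)
        assert len(cands) == 2
        assert all(c.fov_status == "straddling" for c in cands)

    def test_circumcircle_contains_image_vertices(self, empty_channel):
        for c in cull_faces(empty_channel, CAM):
            center, radius = c.circumcircle
            d = np.linalg.norm(c.image_triangle - center, axis=1)
            assert np.all(d <= radius + 1e-9)


class TestOccluderDetection:
    def test_stacked_plates_occlusion_is_asymmetric(self, stacked_plates):
        cands = find_occluders(cull_faces(stacked_plates, CAM), CAM)
        by_index = {c.index: c for c in cands}
        lower = [by_index[i] for i in (0, 1)]
        upper = [by_index[i] for i in (2, 3)]
        assert all(set(c.occluder_list) & {2, 3} for c in lower)
        assert all(not c.occluder_list for c in upper)

    def test_laterally_separated_plates_have_empty_lists(self):
        a = square_plate(half=1.0)
        b = square_plate(half=1.0, z=10.0)
        b.vertices = b.vertices + np.array([10.0, 0.0, 0.0])
        mesh = TriangleMesh(
            vertices=np.vstack([a.vertices, b.vertices]),
            faces=np.vstack([a.faces, b.faces + 4]),
        )
        cands = find_occluders(cull_faces(mesh, CAM), CAM)
        assert all(not c.occluder_list for c in cands)

    def test_matches_brute_force_on_random_scenes(self):
        rng = np.random.default_rng(19)
        for _ in range(6):
            tris = []
            for _k in range(50):
                base = rng.uniform([-10, -10, 0], [10, 10, 30])
                tri = base + rng.uniform(-3, 3, size=(3, 3))
                n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
                if np.linalg.norm(n) < 1e-6:
                    continue
                if (n / np.linalg.norm(n)) @ CAM.view_dir > 0:
                    tri = tri[::-1]
                tris.append(tri)
            tris = np.array(tris)
            mesh = TriangleMesh(
                vertices=tris.reshape(-1, 3),
                faces=np.arange(tris.size // 3).reshape(-1, 3),
            )
            cands = find_occluders(cull_faces(mesh, CAM), CAM)
            got = {c.index: set(c.occluder_list) for c in cands}

            # brute force: all pairs, no circumcircle prefilter
            expect = {c.index: set() for c in cands}
            eps = 1e-8 * CAM.image_scale**2
            for i, a in enumerate(cands):
                for b in cands[i + 1 :]:
                    inter = shapely.intersection(
                        Polygon(a.image_triangle), Polygon(b.image_triangle)
                    ).area
                    if inter <= eps or abs(a.min_depth - b.min_depth) <= 1e-9:
                        continue
                    if a.min_depth > b.min_depth:
                        expect[a.index].add(b.index)
                    else:
                        expect[b.index].add(a.index)
            assert got == expect


class TestClipping:
    def test_inside_face_passes_unchanged(self, plate):
        cands = cull_faces(plate, CAM)
        assert cands[0].fov_status == "inside"

    def test_symmetric_straddle_clips_to_half(self):
        cam = make_ring_setup(1, 1e-9, 400).cameras[0]
        # triangle symmetric about the x = 18 mm FOV border line
        v = np.array([[12.0, -5.0, 0.0], [24.0, -5.0, 0.0], [18.0, 5.0, 0.0]])
        mesh = TriangleMesh(vertices=v, faces=[[0, 1, 2]])
        (cand,) = cull_faces(mesh, cam)
        assert cand.fov_status == "straddling"
        frag = clip_to_fov(cand, cam)
        assert frag.area == pytest.approx(0.5 * Polygon(cand.image_triangle).area)

    def test_fully_covered_face_is_invisible(self):
        lower = square_plate(half=5.0, z=0.0)
        upper = square_plate(half=10.0, z=10.0)
        mesh = TriangleMesh(
            vertices=np.vstack([lower.vertices, upper.vertices]),
            faces=np.vstack([lower.faces, upper.faces + 4]),
        )
        vmap = visible_subset(mesh, CAM)
        assert 0 not in vmap.fragments and 1 not in vmap.fragments
        assert vmap.total_area() == pytest.approx(400.0)

    def test_half_covering_occluder_leaves_half(self):
        # occluder plate covers x <= 0 over a focal-plane subject plate
        subject = square_plate(half=5.0, z=0.0)
        occ = np.array(
            [[-15.0, -15.0, 20.0], [0.0, -15.0, 20.0], [0.0, 15.0, 20.0], [-15.0, 15.0, 20.0]]
        )
        cam = make_ring_setup(1, 1e-9, 400).cameras[0]
        # under an overhead camera the shadow boundary maps to x = 0 exactly
        mesh = TriangleMesh(
            vertices=np.vstack([subject.vertices, occ]),
            faces=np.vstack([subject.faces, [[4, 5, 6], [4, 6, 7]]]),
        )
        vmap = visible_subset(mesh, cam)
        visible_subject = sum(vmap.fragments[i].area for i in (0, 1) if i in vmap.fragments)
        assert visible_subject == pytest.approx(50.0, rel=1e-9)


class TestVisibleSubset:
    def test_open_plate_fully_visible(self, plate):
        vmap = visible_subset(plate, CAM)
        assert vmap.total_area() == pytest.approx(400.0, rel=1e-12)

    def test_fragment_areas_never_exceed_face_areas(self, artery_channel):
        vmap = visible_subset(artery_channel, SETUP4.cameras[1])
        areas = artery_channel.face_areas()
        for i, frag in vmap.fragments.items():
            assert frag.area <= areas[i] + 1e-8

    def test_face_order_insensitivity(self, empty_channel):
        rng = np.random.default_rng(5)
        perm = rng.permutation(empty_channel.n_faces)
        shuffled = TriangleMesh(
            vertices=empty_channel.vertices,
            faces=empty_channel.faces[perm],
            tags=empty_channel.tags[perm],
        )
        a = visible_subset(empty_channel, CAM).total_area()
        b = visible_subset(shuffled, CAM).total_area()
        assert b == pytest.approx(a, rel=1e-7)

    def test_channel_wall_visibility_matches_analytic_section(self, empty_channel):
        """Single camera, unconstrained FOV: the visible wall band of the
        empty cylinder must match the rim-shadow integral.

        A wall point at azimuth phi, height z is visible iff the wall is
        front-facing there and the ray to the aperture exits through the
        channel opening; the shadow height z_min(phi) follows from the
        ray-opening intersection and the visible area is the integral of
        (depth - z_min) R dphi over the front-facing range.
        """
        from scipy.integrate import quad
        from scipy.optimize import brentq

        cam = make_ring_setup(1, 30, 400, fov_spec=(500.0, 500.0)).cameras[0]
        a = cam.aperture
        R, D = 12.5, 50.0

        def shadow_z(phi):
            p_xy = np.array([R * np.cos(phi), R * np.sin(phi)])

            def open_violation(z):
                s = (D - z) / (a[2] - z)
                q = p_xy + (a[:2] - p_xy) * s
                return np.hypot(*q) - R

            if open_violation(0.0) <= 0.0:
                return 0.0
            z_hi = D - 1e-9  # at z = D the ray exits exactly on the rim
            if open_violation(z_hi) >= 0.0:
                return D
            return brentq(open_violation, 0.0, z_hi)

        def band(phi):
            if a[0] * np.cos(phi) + a[1] * np.sin(phi) >= 0.0:
                return 0.0  # backface/contour at this azimuth
            return D - shadow_z(phi)

        exact, _ = quad(band, 0.0, 2.0 * np.pi, limit=400)
        exact *= R
        vmap = visible_subset(empty_channel, cam)
        wall = sum(f.area for f in vmap.fragments.values() if f.tag == "wall")
        assert wall == pytest.approx(exact, rel=0.02)

    def test_more_cameras_see_at_least_as_much(self, empty_channel):
        single = visible_subset(empty_channel, SETUP4.cameras[0])
        union_faces = set()
        for cam in SETUP4.cameras:
            union_faces |= set(visible_subset(empty_channel, cam).fragments)
        assert set(single.fragments) <= union_faces
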