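"""Per-camera visibility: culling, occluder detection, clipping.

For one camera the pipeline runs in the order: invisibility culling
(backfaces/contour faces, then faces fully outside the FOV), occluder
detection (circumcircle broad phase in image space, positive-area image
overlap narrow phase, minimal-depth ordering), clipping to the FOV
rectangle where needed, and finally clipping against the merged images of
the known occluders.  The surviving region of each face is back-projected
onto the face's plane and stored in the face's local 2D frame, where its
area is the true 3D area.

The minimal depth of a face is the smallest *Euclidean* distance from the
aperture to any of its vertices (not the axial depth).  Overlapping faces
whose minimal depths tie exactly (e.g. neighbours sharing their nearest
vertex, folding over each other near a silhouette) are ordered by mean
vertex depth instead; a pair tied in both measures is skipped with a
warning, since no per-face ordering can be justified there.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from . import geometry2d as g2
from .camera import Camera
from .errors import ProjectionDomainError
from .mesh_io import TriangleMesh

__all__ = [
    "CandidateFace",
    "FaceFragments",
    "VisibilityMap",
    "cull_faces",
    "find_occluders",
    "clip_to_fov",
    "clip_against_occluders",
    "visible_subset",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CandidateFace:
    """A face that survived culling, with its image-space bookkeeping."""

    index: int
    image_triangle: np.ndarray
    min_depth: float
    mean_depth: float
    fov_status: str  # "inside" | "straddling"
    circumcircle: tuple[np.ndarray, float]
    occluder_list: list[int] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class FaceFragments:
    """Visible fragments of one face in its local in-plane frame.

    ``full`` marks the unclipped fast path (the whole face is visible);
    ``polygon`` is then the face's own local triangle.  Local-frame areas
    equal 3D areas (the frame map is an isometry).
    """

    index: int
    frame: g2.LocalFrame
    polygon: Polygon
    tag: str
    full: bool

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclasses.dataclass
class VisibilityMap:
    """Per-face visible fragments for a single camera (absent face = empty)."""

    camera: Camera
    fragments: dict[int, FaceFragments]

    def total_area(self) -> float:
        return sum(f.area for f in self.fragments.values())


# ---------------------------------------------------------------------------
# per-mesh cached derived data (local frames and local triangles)
# ---------------------------------------------------------------------------

class _MeshCache:
    def __init__(self, mesh: TriangleMesh):
        tri = mesh.triangles()
        o = tri[:, 0]
        e1 = tri[:, 1] - o
        l1 = np.linalg.norm(e1, axis=1)
        x_axis = e1 / np.where(l1 > 0, l1, 1.0)[:, None]
        n = np.cross(x_axis, tri[:, 2] - o)
        ln = np.linalg.norm(n, axis=1)
        normal = n / np.where(ln > 0, ln, 1.0)[:, None]
        y_axis = np.cross(normal, x_axis)
        v3 = tri[:, 2] - o
        self.origins = o
        self.x_axes = x_axis
        self.y_axes = y_axis
        self.normals = normal
        self.local_tris = np.zeros((len(tri), 3, 2))
        self.local_tris[:, 1, 0] = l1
        self.local_tris[:, 2, 0] = np.einsum("ij,ij->i", v3, x_axis)
        self.local_tris[:, 2, 1] = np.einsum("ij,ij->i", v3, y_axis)
        self._frames: dict[int, g2.LocalFrame] = {}
        self._local_polys: dict[int, Polygon] = {}

    def frame(self, i: int) -> g2.LocalFrame:
        fr = self._frames.get(i)
        if fr is None:
            fr = g2.LocalFrame(
                origin=self.origins[i],
                x_axis=self.x_axes[i],
                y_axis=self.y_axes[i],
                normal=self.normals[i],
            )
            self._frames[i] = fr
        return fr

    def local_poly(self, i: int) -> Polygon:
        p = self._local_polys.get(i)
        if p is None:
            p = Polygon(self.local_tris[i])
            self._local_polys[i] = p
        return p


def mesh_cache(mesh: TriangleMesh) -> _MeshCache:
    cache = getattr(mesh, "_reconsim_cache", None)
    if cache is None:
        cache = _MeshCache(mesh)
        mesh._reconsim_cache = cache
    return cache


# ---------------------------------------------------------------------------
# stage 1: culling
# ---------------------------------------------------------------------------

def _circumcircles(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized enclosing circles of image triangles.

    The circumcenter is used where well-conditioned; near-degenerate
    triangles fall back to the centroid.  The radius is always the largest
    center-to-vertex distance, so the circle provably contains the triangle
    either way (the broad phase stays conservative).
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    scale = np.max(np.abs(tris.reshape(len(tris), -1)), axis=1) + 1e-300
    ok = np.abs(d) > 1e-12 * scale**2
    a2 = np.einsum("ij,ij->i", a, a)
    b2 = np.einsum("ij,ij->i", b, b)
    c2 = np.einsum("ij,ij->i", c, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    centers = np.where(ok[:, None], np.column_stack([ux, uy]), tris.mean(axis=1))
    radii = np.linalg.norm(tris - centers[:, None, :], axis=2).max(axis=1) + g2.IMAGE_TOL
    return centers, radii


def cull_faces(mesh: TriangleMesh, camera: Camera) -> list[CandidateFace]:
    """Eliminate backfaces/contour faces and faces fully outside the FOV.

    A face survives the orientation test iff the dot product of its normal
    with the viewing direction toward the scene is strictly negative (zero
    dot = contour face, by definition invisible).  Faces whose image
    straddles the FOV border are flagged for clipping.
    """
    verts = mesh.vertices
    cam_xyz = verts @ camera.mext[:, :3].T + camera.mext[:, 3]
    w = cam_xyz[:, 2]
    if np.any(w <= 1e-9):
        raise ProjectionDomainError("mesh vertex at or behind the aperture plane")
    img = np.column_stack(
        [camera.mint[0, 0] * cam_xyz[:, 0] / w, camera.mint[1, 1] * cam_xyz[:, 1] / w]
    )
    keep = (mesh.normals @ camera.view_dir) < 0.0
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return []
    tris = img[mesh.faces[idx]]  # (K, 3, 2)
    hw, hh = camera.fov_halfwidth, camera.fov_halfheight

    inside = np.all(
        (np.abs(tris[:, :, 0]) <= hw) & (np.abs(tris[:, :, 1]) <= hh), axis=1
    )
    bbox_out = (
        (tris[:, :, 0].max(axis=1) < -hw)
        | (tris[:, :, 0].min(axis=1) > hw)
        | (tris[:, :, 1].max(axis=1) < -hh)
        | (tris[:, :, 1].min(axis=1) > hh)
    )
    maybe = ~inside & ~bbox_out
    eps_img = g2.AREA_EPS * camera.image_scale**2
    straddle = np.zeros(len(idx), dtype=bool)
    if maybe.any():
        fov_box = box(-hw, -hh, hw, hh)
        rings = np.concatenate([tris[maybe], tris[maybe][:, :1]], axis=1)
        polys = shapely.polygons(rings)
        inter = shapely.area(shapely.intersection(polys, fov_box))
        straddle[np.flatnonzero(maybe)] = inter > eps_img

    survivors = inside | straddle
    dist = np.linalg.norm(verts - camera.aperture, axis=1)
    min_depth = dist[mesh.faces[idx]].min(axis=1)
    mean_depth = dist[mesh.faces[idx]].mean(axis=1)
    centers, radii = _circumcircles(tris)

    out = []
    for k in np.flatnonzero(survivors):
        out.append(
            CandidateFace(
                index=int(idx[k]),
                image_triangle=tris[k],
                min_depth=float(min_depth[k]),
                mean_depth=float(mean_depth[k]),
                fov_status="inside" if inside[k] else "straddling",
                circumcircle=(centers[k], float(radii[k])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage 2: occluder detection
# ---------------------------------------------------------------------------

def find_occluders(candidates: list[CandidateFace], camera: Camera) -> list[CandidateFace]:
    """Fill each candidate's list of known occluders (face indices).

    Pairs are pre-filtered by circumcircle overlap, confirmed by a
    positive-area overlap of the image triangles, and ordered by minimal
    depth: the deeper face of a confirmed pair is the occludee.
    """
    K = len(candidates)
    if K < 2:
        return candidates
    centers = np.array([c.circumcircle[0] for c in candidates])
    radii = np.array([c.circumcircle[1] for c in candidates])
    depths = np.array([c.min_depth for c in candidates])
    mean_depths = np.array([c.mean_depth for c in candidates])
    tris = np.array([c.image_triangle for c in candidates])

    diff = centers[:, None, :] - centers[None, :, :]
    close = (diff**2).sum(axis=2) <= (radii[:, None] + radii[None, :]) ** 2
    iu = np.triu_indices(K, k=1)
    pair_mask = close[iu]
    # bbox rejection sharpens the broad phase (cheap, still conservative)
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    bbox_sep = (
        (hi[iu[0], 0] < lo[iu[1], 0])
        | (hi[iu[1], 0] < lo[iu[0], 0])
        | (hi[iu[0], 1] < lo[iu[1], 1])
        | (hi[iu[1], 1] < lo[iu[0], 1])
    )
    pair_mask &= ~bbox_sep
    ii, jj = iu[0][pair_mask], iu[1][pair_mask]
    if len(ii) == 0:
        return candidates

    rings = np.concatenate([tris, tris[:, :1]], axis=1)
    polys = shapely.polygons(rings)
    eps_img = g2.AREA_EPS * camera.image_scale**2
    inter = shapely.area(shapely.intersection(polys[ii], polys[jj]))
    overlap = inter > eps_img

    for a, b_ in zip(ii[overlap], jj[overlap]):
        da, db = depths[a], depths[b_]
        if abs(da - db) <= g2.DEPTH_TIE_TOL:
            da, db = mean_depths[a], mean_depths[b_]
            if abs(da - db) <= g2.DEPTH_TIE_TOL:
                logger.warning(
                    "overlapping faces %d/%d tie in minimal and mean depth; "
                    "pair skipped",
                    candidates[a].index,
                    candidates[b_].index,
                )
                continue
        if da > db:
            candidates[a].occluder_list.append(candidates[b_].index)
        else:
            candidates[b_].occluder_list.append(candidates[a].index)
    return candidates


# ---------------------------------------------------------------------------
# stage 3 & 4: clipping
# ---------------------------------------------------------------------------

def clip_to_fov(candidate: CandidateFace, camera: Camera):
    """Intersect a straddling face's image with the FOV rectangle."""
    hw, hh = camera.fov_halfwidth, camera.fov_halfheight
    tri = Polygon(candidate.image_triangle)
    eps_img = g2.AREA_EPS * camera.image_scale**2
    return g2.clean(shapely.intersection(tri, box(-hw, -hh, hw, hh)), eps_img)


def clip_against_occluders(
    candidate: CandidateFace,
    fragments,
    camera: Camera,
    occluder_images: dict[int, Polygon],
    frame: g2.LocalFrame,
    tag: str = "",
):
    """Subtract the merged occluder images and return the face's visible
    fragments in its local frame, or ``None`` if nothing remains."""
    eps_img = g2.AREA_EPS * camera.image_scale**2
    if candidate.occluder_list:
        merged = shapely.union_all([occluder_images[j] for j in candidate.occluder_list])
        fragments = g2.clean(shapely.difference(fragments, merged), eps_img)
    if fragments.is_empty:
        return None
    local = g2.polygon_to_frame(camera, fragments, frame)
    if local.is_empty:
        return None
    return FaceFragments(
        index=candidate.index, frame=frame, polygon=local, tag=tag, full=False
    )


def visible_subset(mesh: TriangleMesh, camera: Camera) -> VisibilityMap:
    """The portion of every face visible to one camera.

    Composition of the four stages in order: culling, occluder detection,
    FOV clipping, occlusion clipping.  Faces that are fully inside the FOV
    with no occluders take a fast path and are stored as their own local
    triangle.
    """
    candidates = find_occluders(cull_faces(mesh, camera), camera)
    cache = mesh_cache(mesh)
    tags = [str(t) for t in mesh.tags]
    tri_polys = {c.index: Polygon(c.image_triangle) for c in candidates}

    fragments: dict[int, FaceFragments] = {}
    for cand in candidates:
        i = cand.index
        if cand.fov_status == "inside" and not cand.occluder_list:
            fragments[i] = FaceFragments(
                index=i,
                frame=cache.frame(i),
                polygon=cache.local_poly(i),
                tag=tags[i],
                full=True,
            )
            continue
        frag_img = (
            clip_to_fov(cand, camera) if cand.fov_status == "straddling" else tri_polys[i]
        )
        if frag_img.is_empty:
            continue
        entry = clip_against_occluders(
            cand, frag_img, camera, tri_polys, cache.frame(i), tags[i]
        )
        if entry is not None:
            fragments[i] = entry
    return VisibilityMap(camera=camera, fragments=fragments)
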