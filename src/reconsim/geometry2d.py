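"""Local planar frames, 2.5D transforms and robust 2D polygon booleans.

All polygon clipping in the pipeline happens in 2D: either in a camera's
image space or in a face's local in-plane frame.  The in-plane frame is an
isometry, so 2D areas there equal 3D areas directly.  Shapely (GEOS) is the
boolean kernel; every result passes through :func:`clean` which repairs
topology and discards sliver rings below ``AREA_EPS``.

Tolerance registry (used project-wide):

* ``POSITION_TOL`` -- 1e-9 mm absolute for 3D point comparisons,
* ``IMAGE_TOL`` -- 1e-9 image units,
* ``AREA_EPS`` -- 1e-8 mm^2, the sliver cut-off for clipped fragments
  (far below any reported area increment, well above float noise),
* ``DEPTH_TIE_TOL`` -- 1e-9 mm for occlusion-ordering depth ties.

Boundary-touching polygons (zero-area intersection) count as *not*
overlapping, which keeps adjacent mesh faces from becoming mutual occluders.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .camera import Camera, project_point, unproject_dirs
from .errors import DegenerateGeometryError, GeometryError

__all__ = [
    "POSITION_TOL",
    "IMAGE_TOL",
    "AREA_EPS",
    "DEPTH_TIE_TOL",
    "LocalFrame",
    "local_frame",
    "to_local",
    "from_local",
    "boolean_2d",
    "polygon_area",
    "clean",
    "back_project",
    "back_project_rings",
    "polygon_to_frame",
    "iter_polygons",
]

POSITION_TOL = 1e-9
IMAGE_TOL = 1e-9
AREA_EPS = 1e-8
DEPTH_TIE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class LocalFrame:
    """Orthonormal 2D coordinate system in the plane of a parent face.

    Origin is the first face vertex, ``x_axis`` points along the first edge,
    ``normal`` matches the winding normal and ``y_axis = normal x x_axis``.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    normal: np.ndarray


def local_frame(face) -> LocalFrame:
    """Construct the in-plane frame of a triangle given as a (3, 3) array.

    ``o' = v1``, ``x' = (v2 - o')/|v2 - o'|``, ``n = x' x (v3 - o')``
    normalized (this is the winding normal), ``y' = n x x'``.
    """
    v = np.asarray(face, dtype=float)
    o = v[0]
    e1 = v[1] - o
    n1 = np.linalg.norm(e1)
    if n1 <= POSITION_TOL:
        raise DegenerateGeometryError("degenerate face: coincident vertices")
    x_axis = e1 / n1
    n = np.cross(x_axis, v[2] - o)
    nn = np.linalg.norm(n)
    if nn <= POSITION_TOL:
        raise DegenerateGeometryError("degenerate face: collinear vertices")
    normal = n / nn
    y_axis = np.cross(normal, x_axis)
    return LocalFrame(origin=o, x_axis=x_axis, y_axis=y_axis, normal=normal)


def to_local(frame: LocalFrame, p3, check: bool = False, tol: float = 1e-6) -> np.ndarray:
    """Map 3D in-plane point(s) to 2D frame coordinates.

    With ``check=True`` an out-of-plane distance beyond ``tol`` (mm) raises.
    """
    p = np.asarray(p3, dtype=float)
    rel = p - frame.origin
    if check:
        off = np.abs(rel @ frame.normal)
        if np.max(off) > tol:
            raise DegenerateGeometryError(
                f"point lies {np.max(off):.3g} mm out of the frame plane"
            )
    return np.stack([rel @ frame.x_axis, rel @ frame.y_axis], axis=-1)


def from_local(frame: LocalFrame, p2) -> np.ndarray:
    """Map 2D frame coordinate(s) back to 3D world points."""
    p = np.asarray(p2, dtype=float)
    return (
        frame.origin
        + np.multiply.outer(p[..., 0], frame.x_axis)
        + np.multiply.outer(p[..., 1], frame.y_axis)
    )


def clean(geom: BaseGeometry, area_eps: float = AREA_EPS) -> BaseGeometry:
    """Repair topology and drop rings/parts below the sliver threshold."""
    if geom.is_empty:
        return Polygon()
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    parts = []
    for poly in iter_polygons(geom):
        if poly.area < area_eps:
            continue
        holes = [h for h in poly.interiors if Polygon(h).area >= area_eps]
        parts.append(Polygon(poly.exterior, holes))
    if not parts:
        return Polygon()
    if len(parts) == 1:
        return parts[0]
    out = shapely.union_all(parts)
    if not out.is_valid:
        raise GeometryError(f"invalid ring topology after cleaning: {out.wkt[:200]}")
    return out


def iter_polygons(geom: BaseGeometry):
    """Yield the Polygon parts of a (Multi)Polygon / GeometryCollection."""
    if geom.is_empty:
        return
    if isinstance(geom, Polygon):
        yield geom
    elif isinstance(geom, MultiPolygon):
        yield from geom.geoms
    else:
        for g in getattr(geom, "geoms", []):
            yield from iter_polygons(g)


def boolean_2d(op: str, a: BaseGeometry, b: BaseGeometry, area_eps: float = AREA_EPS):
    """Set operation (``intersect``/``subtract``/``union``) on polygon sets."""
    if op == "intersect":
        out = shapely.intersection(a, b)
    elif op == "subtract":
        out = shapely.difference(a, b)
    elif op == "union":
        out = shapely.union(a, b)
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return clean(out, area_eps)


def polygon_area(geom: BaseGeometry) -> float:
    """Nonnegative area with holes subtracted (mm^2 in a local frame)."""
    return float(geom.area)


def _plane_of(plane):
    if isinstance(plane, LocalFrame):
        return plane.origin, plane.normal
    point, normal = plane
    return np.asarray(point, dtype=float), np.asarray(normal, dtype=float)


def back_project_rings(camera: Camera, rings_2d, plane) -> list[np.ndarray]:
    """Back-project 2D image-space rings onto a 3D plane.

    Each image vertex defines a ray from the aperture; the 3D vertex is the
    intersection of that ray with the plane.  Raises
    :class:`DegenerateGeometryError` for rays parallel to the plane or a
    plane through the aperture.
    """
    point, normal = _plane_of(plane)
    denom_origin = float((point - camera.aperture) @ normal)
    out = []
    for ring in rings_2d:
        ring = np.asarray(ring, dtype=float)
        dirs = unproject_dirs(camera, ring)
        denom = dirs @ normal
        if np.any(np.abs(denom) <= POSITION_TOL * np.linalg.norm(normal)):
            raise DegenerateGeometryError("vertex ray parallel to the target plane")
        t = denom_origin / denom
        out.append(camera.aperture + t[:, None] * dirs)
    return out


def back_project(camera: Camera, image_polygon: Polygon, plane) -> Polygon:
    """Back-project an image-space polygon onto a plane; returns a polygon
    with 3D (x, y, z) coordinates, holes preserved."""
    rings = [np.asarray(image_polygon.exterior.coords)[:-1]]
    rings += [np.asarray(h.coords)[:-1] for h in image_polygon.interiors]
    pts3 = back_project_rings(camera, rings, plane)
    return Polygon(pts3[0], [r for r in pts3[1:]])


def polygon_to_frame(camera: Camera, image_geom: BaseGeometry, frame: LocalFrame):
    """Back-project an image-space polygon set onto a face plane and express
    it in the face's local 2D frame (areas then read in mm^2)."""
    parts = []
    for poly in iter_polygons(image_geom):
        rings = [np.asarray(poly.exterior.coords)[:-1]]
        rings += [np.asarray(h.coords)[:-1] for h in poly.interiors]
        pts3 = back_project_rings(camera, rings, frame)
        local = [to_local(frame, r) for r in pts3]
        parts.append(Polygon(local[0], local[1:]))
    if not parts:
        return Polygon()
    return clean(shapely.union_all(parts) if len(parts) > 1 else parts[0])
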