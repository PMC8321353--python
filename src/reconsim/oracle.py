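"""Brute-force Monte-Carlo verification of the exact pipeline.

Independent of the clipping pipeline: surface points are sampled
area-uniformly, and visibility per camera is decided by ray casting —
a point is visible iff its source face is front-facing, the point projects
inside the FOV rectangle, and the segment from the point (nudged off the
surface along its face normal) to the aperture intersects no other mesh
triangle.  The ray-triangle test is a vectorized Moller-Trumbore with the
source face excluded by id.  Orders of magnitude slower than the pipeline;
used by tests and the acceptance checks.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .camera import Camera, RingSetup
from .mesh_io import TriangleMesh

__all__ = [
    "OracleEstimate",
    "sample_surface",
    "visibility_counts",
    "ray_visible",
    "mc_visible_fraction",
    "mc_reconstructable_fraction",
]

#: normal offset of ray origins off the surface (mm)
_EPS_OFFSET = 1e-6
#: minimum ray parameter (fraction of point-to-aperture distance) for a hit;
#: rejects re-hits of coplanar neighbours at the origin while the nearest
#: genuine occluder in any scene at this scale is orders of magnitude farther
_T_MIN = 1e-5


@dataclasses.dataclass(frozen=True)
class OracleEstimate:
    n_samples: int
    hits: int
    fraction: float
    se: float
    seed: int


def sample_surface(mesh: TriangleMesh, n_samples: int, seed: int):
    """Area-uniform surface samples: per-face allocation by cumulative area
    inversion, uniform barycentric placement within each face.

    Returns ``(points (n, 3), face_ids (n,))``.
    """
    rng = np.random.default_rng(seed)
    areas = mesh.face_areas()
    cdf = np.cumsum(areas)
    face_ids = np.searchsorted(cdf, rng.uniform(0.0, cdf[-1], size=n_samples))
    tri = mesh.triangles()[face_ids]
    r1 = np.sqrt(rng.uniform(size=n_samples))
    r2 = rng.uniform(size=n_samples)
    points = (
        (1.0 - r1)[:, None] * tri[:, 0]
        + (r1 * (1.0 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )
    return points, face_ids


def _segments_occluded(
    origins: np.ndarray,
    target: np.ndarray,
    exclude_ids: np.ndarray,
    tri: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """True where the segment origin->target hits any triangle other than
    the excluded source triangle (Moller-Trumbore, batched)."""
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    n = len(origins)
    occluded = np.zeros(n, dtype=bool)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        O = origins[lo:hi]
        D = target - O  # t in (0, 1) spans the segment
        h = np.cross(D[:, None, :], e2[None, :, :])
        a = np.einsum("fj,rfj->rf", e1, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(np.abs(a) > 1e-300, 1.0 / a, 0.0)
        s = O[:, None, :] - v0[None, :, :]
        u = f * np.einsum("rfj,rfj->rf", s, h)
        q = np.cross(s, e1[None, :, :])
        v = f * np.einsum("rj,rfj->rf", D, q)
        t = f * np.einsum("fj,rfj->rf", e2, q)
        hit = (
            (np.abs(a) > 1e-300)
            & (u >= -1e-12)
            & (v >= -1e-12)
            & (u + v <= 1.0 + 1e-12)
            & (t > _T_MIN)
            & (t < 1.0)
        )
        hit[np.arange(hi - lo), exclude_ids[lo:hi]] = False
        occluded[lo:hi] = hit.any(axis=1)
    return occluded


def visibility_counts(
    mesh: TriangleMesh, cameras, points: np.ndarray, face_ids: np.ndarray
) -> np.ndarray:
    """(n_points, n_cameras) boolean visibility matrix by ray casting."""
    tri = mesh.triangles()
    normals = mesh.normals[face_ids]
    origins = points + _EPS_OFFSET * normals
    out = np.zeros((len(points), len(cameras)), dtype=bool)
    for j, cam in enumerate(cameras):
        front = (mesh.normals @ cam.view_dir)[face_ids] < 0.0
        cam_xyz = points @ cam.mext[:, :3].T + cam.mext[:, 3]
        w = cam_xyz[:, 2]
        img_u = cam.mint[0, 0] * cam_xyz[:, 0] / w
        img_v = cam.mint[1, 1] * cam_xyz[:, 1] / w
        in_fov = (
            (w > 0)
            & (np.abs(img_u) <= cam.fov_halfwidth)
            & (np.abs(img_v) <= cam.fov_halfheight)
        )
        mask = front & in_fov
        if mask.any():
            occ = _segments_occluded(
                origins[mask], cam.aperture, face_ids[mask], tri
            )
            vis = np.zeros(len(points), dtype=bool)
            vis[np.flatnonzero(mask)[~occ]] = True
            out[:, j] = vis
    return out


def ray_visible(point, face_index: int, camera: Camera, mesh: TriangleMesh) -> bool:
    """Visibility of a single surface point to a single camera."""
    pts = np.asarray(point, dtype=float)[None, :]
    ids = np.array([face_index])
    return bool(visibility_counts(mesh, [camera], pts, ids)[0, 0])


def _estimate(counts_ok: np.ndarray, seed: int) -> OracleEstimate:
    n = len(counts_ok)
    hits = int(counts_ok.sum())
    p = hits / n
    return OracleEstimate(
        n_samples=n, hits=hits, fraction=p, se=math.sqrt(p * (1.0 - p) / n), seed=seed
    )


def mc_visible_fraction(
    mesh: TriangleMesh, camera: Camera, n_samples: int, seed: int
) -> OracleEstimate:
    """Fraction of the total surface area visible to one camera."""
    points, face_ids = sample_surface(mesh, n_samples, seed)
    counts = visibility_counts(mesh, [camera], points, face_ids)
    return _estimate(counts[:, 0], seed)


def mc_reconstructable_fraction(
    mesh: TriangleMesh, setup: RingSetup, T: int, n_samples: int, seed: int
) -> OracleEstimate:
    """Fraction of the total surface area visible to at least T cameras;
    estimates ``Ar / total_area`` independently of the exact pipeline."""
    points, face_ids = sample_surface(mesh, n_samples, seed)
    counts = visibility_counts(mesh, setup.cameras, points, face_ids)
    return _estimate(counts.sum(axis=1) >= T, seed)
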