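"""Pinhole cameras on a confocal ring.

Models the camera side of a common-main-objective (CMO) surgical microscope:
the microscope optics are idealized away and each observation channel becomes
a pinhole camera sitting on a ring of diameter ``d`` (the maximum usable
stereo baseline, 20-30 mm in real CMO heads) at working distance ``h`` above
a common reference point ``F``.  Every camera looks at ``F``, so all
principal rays intersect there and all apertures are equidistant from ``F``
(the simulated CMO focal length ``sqrt(h^2 + (d/2)^2)``).

Conventions
-----------
* The look-at axis ``l`` points from the reference point toward the aperture,
  i.e. *away* from the scene; the viewing direction toward the scene is
  ``-l``.  The extrinsic rotation rows are ``(r, u, -l)`` so that scene
  points have a positive third (depth) camera coordinate.
* The intrinsic matrix has a negative diagonal ``(-f/sx, -f/sy)``, zero skew
  and zero principal-point offset.  Sensor resolution never enters the area
  computation; only the focal-plane FOV rectangle does.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateGeometryError, ProjectionDomainError

__all__ = [
    "CameraFrame",
    "Camera",
    "RingSetup",
    "look_at_axes",
    "extrinsic_matrix",
    "intrinsic_matrix",
    "project_point",
    "unproject_dirs",
    "fov_rectangle",
    "make_camera",
    "make_ring_setup",
]

#: minimum sine of the angle between the up hint and the viewing axis
_UP_HINT_TOL = 1e-9
#: minimum admissible projective depth (mm)
_DEPTH_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class CameraFrame:
    """Orthonormal look-at frame of a single camera.

    ``lookat`` is the unit vector from the reference point toward the
    aperture; the camera views the scene along ``-lookat``.
    """

    aperture: np.ndarray
    right: np.ndarray
    up_axis: np.ndarray
    lookat: np.ndarray
    reference: np.ndarray


@dataclasses.dataclass(frozen=True)
class Camera:
    """A pinhole camera with pose, matrices and FOV rectangle.

    ``fov_halfwidth``/``fov_halfheight`` are image-space half extents whose
    back-projection onto the focal plane (the plane through the reference
    point normal to the viewing axis) spans the configured FOV rectangle.
    """

    frame: CameraFrame
    mext: np.ndarray
    mint: np.ndarray
    pmat: np.ndarray
    f: float
    sx: float
    sy: float
    fov_halfwidth: float
    fov_halfheight: float

    @property
    def aperture(self) -> np.ndarray:
        return self.frame.aperture

    @property
    def view_dir(self) -> np.ndarray:
        """Unit viewing direction toward the scene (``-lookat``)."""
        return -self.frame.lookat

    @property
    def distance_to_reference(self) -> float:
        return float(np.linalg.norm(self.frame.aperture - self.frame.reference))

    @property
    def image_scale(self) -> float:
        """Image units per mm in the focal plane (``f / (sx * |a - F|)``)."""
        return self.f / (self.sx * self.distance_to_reference)


@dataclasses.dataclass(frozen=True)
class RingSetup:
    """An ordered set of confocal cameras spaced equidistantly on a ring."""

    cameras: tuple[Camera, ...]
    d: float
    h: float
    reference: np.ndarray
    start_angle: float

    @property
    def M(self) -> int:
        return len(self.cameras)

    def subset(self, indices) -> "RingSetup":
        """A setup restricted to the given camera indices (order preserved)."""
        cams = tuple(self.cameras[i] for i in indices)
        return dataclasses.replace(self, cameras=cams)


def look_at_axes(a, F, up_hint=(0.0, 1.0, 0.0)) -> CameraFrame:
    """Build the orthonormal camera frame for an aperture ``a`` looking at ``F``.

    ``l = (a - F)/|a - F|`` (away from the scene), ``r = up_hint x l``
    normalized, ``u = l x r``.  Raises :class:`DegenerateGeometryError` when
    the up hint is parallel to the viewing axis.
    """
    a = np.asarray(a, dtype=float)
    F = np.asarray(F, dtype=float)
    diff = a - F
    norm = np.linalg.norm(diff)
    if norm <= _DEPTH_TOL:
        raise DegenerateGeometryError("aperture coincides with the reference point")
    lookat = diff / norm
    up_hint = np.asarray(up_hint, dtype=float)
    r = np.cross(up_hint, lookat)
    r_norm = np.linalg.norm(r)
    if r_norm <= _UP_HINT_TOL * np.linalg.norm(up_hint):
        raise DegenerateGeometryError(
            "up hint is parallel to the viewing axis; supply a different hint"
        )
    right = r / r_norm
    up_axis = np.cross(lookat, right)
    return CameraFrame(aperture=a, right=right, up_axis=up_axis, lookat=lookat, reference=F)


def extrinsic_matrix(frame: CameraFrame) -> np.ndarray:
    """3x4 extrinsic matrix ``[R | t]`` with rows ``(r, u, -l)``, ``t = -R a``."""
    R = np.vstack([frame.right, frame.up_axis, -frame.lookat])
    t = -R @ frame.aperture
    return np.hstack([R, t[:, None]])


def intrinsic_matrix(f: float, sx: float, sy: float) -> np.ndarray:
    """Intrinsic matrix ``diag(-f/sx, -f/sy, 1)`` (zero skew and offset)."""
    if f <= 0 or sx <= 0 or sy <= 0:
        raise ValueError("f, sx and sy must be positive")
    return np.array([[-f / sx, 0.0, 0.0], [0.0, -f / sy, 0.0], [0.0, 0.0, 1.0]])


def fov_rectangle(camera_or_params, fov_spec) -> tuple[float, float]:
    """Image-space half extents of an FOV given as (width, height) mm in the
    focal plane.

    By similar triangles a focal-plane offset ``w`` maps to image offset
    ``w * f / (sx * |a - F|)``, so the half extents are
    ``(W/2 * f/(sx*dist), H/2 * f/(sy*dist))``.
    """
    width, height = float(fov_spec[0]), float(fov_spec[1])
    if width <= 0 or height <= 0:
        raise ValueError("FOV extents must be positive")
    if isinstance(camera_or_params, Camera):
        f, sx, sy = camera_or_params.f, camera_or_params.sx, camera_or_params.sy
        dist = camera_or_params.distance_to_reference
    else:
        f, sx, sy, dist = camera_or_params
    return (0.5 * width * f / (sx * dist), 0.5 * height * f / (sy * dist))


def _build_camera(frame: CameraFrame, fov_spec, f: float, sx: float, sy: float) -> Camera:
    mext = extrinsic_matrix(frame)
    mint = intrinsic_matrix(f, sx, sy)
    dist = float(np.linalg.norm(frame.aperture - frame.reference))
    half_w, half_h = fov_rectangle((f, sx, sy, dist), fov_spec)
    return Camera(
        frame=frame,
        mext=mext,
        mint=mint,
        pmat=mint @ mext,
        f=f,
        sx=sx,
        sy=sy,
        fov_halfwidth=half_w,
        fov_halfheight=half_h,
    )


def project_point(camera: Camera, world_point):
    """Project world point(s) through ``P = Mint @ Mext``.

    Returns ``(image_xy, depth)`` where depth is the distance along the
    viewing axis.  Raises :class:`ProjectionDomainError` for points at or
    behind the aperture plane.
    """
    pts = np.asarray(world_point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    homo = np.hstack([pts, np.ones((len(pts), 1))])
    proj = homo @ camera.pmat.T
    w = proj[:, 2]
    if np.any(w <= _DEPTH_TOL):
        raise ProjectionDomainError("point at or behind the aperture plane")
    img = proj[:, :2] / w[:, None]
    if single:
        return img[0], float(w[0])
    return img, w


def unproject_dirs(camera: Camera, image_points) -> np.ndarray:
    """World-space ray directions (unit depth in camera z) through image points.

    Inverse of the intrinsic map: camera-frame direction
    ``(-u*sx/f, -v*sy/f, 1)`` rotated back to world coordinates; the rays
    originate at the aperture.
    """
    img = np.atleast_2d(np.asarray(image_points, dtype=float))
    dirs_cam = np.column_stack(
        [
            -img[:, 0] * camera.sx / camera.f,
            -img[:, 1] * camera.sy / camera.f,
            np.ones(len(img)),
        ]
    )
    R = camera.mext[:, :3]
    return dirs_cam @ R


def make_camera(
    aperture,
    F=(0.0, 0.0, 0.0),
    fov_spec=(36.0, 24.0),
    f: float = 1.0,
    sx: float = 1.0,
    sy: float = 1.0,
    up_hint=(0.0, 1.0, 0.0),
) -> Camera:
    """A single pinhole camera at an explicit aperture, looking at ``F``."""
    return _build_camera(look_at_axes(aperture, F, up_hint), fov_spec, f, sx, sy)


def make_ring_setup(
    M: int,
    d: float,
    h: float,
    F=(0.0, 0.0, 0.0),
    fov_spec=(36.0, 24.0),
    start_angle: float = 0.0,
    f: float = 1.0,
    sx: float = 1.0,
    sy: float = 1.0,
    up_hint=(0.0, 1.0, 0.0),
) -> RingSetup:
    """Place ``M`` cameras equidistantly on a ring of diameter ``d`` at height
    ``h`` above the common reference point ``F``, all looking at ``F``.

    Camera ``k`` sits at angle ``start_angle + 2*pi*k/M``.  Should the up
    hint degenerate for a particular pose (never the case for the default
    ring and hint), ``(1, 0, 0)`` is used as fallback.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if d <= 0 or h <= 0:
        raise ValueError("ring diameter and working distance must be positive")
    F = np.asarray(F, dtype=float)
    cameras = []
    for k in range(M):
        angle = start_angle + 2.0 * np.pi * k / M
        a = F + np.array([0.5 * d * np.cos(angle), 0.5 * d * np.sin(angle), h])
        try:
            frame = look_at_axes(a, F, up_hint)
        except DegenerateGeometryError:
            frame = look_at_axes(a, F, (1.0, 0.0, 0.0))
        cameras.append(_build_camera(frame, fov_spec, f, sx, sy))
    return RingSetup(
        cameras=tuple(cameras), d=float(d), h=float(h), reference=F, start_angle=float(start_angle)
    )
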