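"""Triangle meshes: binary/ASCII STL I/O, validation and synthetic surgical
sites.

The synthetic generator emulates deep neurosurgical operative corridors: a
rectangular block with a channel of circular (25 mm diameter) or deformed
elliptical (~42.5 x 22.5 mm) cross section, 50 or 100 mm deep, with the
channel floor at z = 0 (the focal plane of the camera ring, where the
surgeon focuses) and the block's top surface at z = +depth facing the
cameras.  Optional anatomy primitives populate the channel: a seeded
low-amplitude relief on the floor, a vessel spanning the channel ~30 mm
above the floor, or a bulge overhanging from the channel wall.  All
generated meshes are watertight and carry per-face tags
(``anatomy``/``wall``/``top_surface``/``exterior``) which clipped fragments
inherit downstream, so area accounting by region stays testable.

Units are millimeters throughout; +z points toward the cameras.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshSpecError, STLFormatError

__all__ = [
    "TriangleMesh",
    "ChannelSpec",
    "ValidationReport",
    "read_binary_stl",
    "write_binary_stl",
    "validate_mesh",
    "make_channel_site",
    "tag_top_surface",
]

_STL_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


@dataclasses.dataclass
class TriangleMesh:
    """A triangle mesh with per-face outward normals and optional tags.

    ``normals`` are recomputed from the counter-clockwise winding unless
    supplied; ``tags`` is a per-face array of short strings (empty string
    for untagged faces).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    tags: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshSpecError("face index out of range")
        if self.normals is None:
            self.normals = self.winding_normals()
        else:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if self.tags is None:
            self.tags = np.full(len(self.faces), "", dtype=object)
        else:
            self.tags = np.asarray(self.tags, dtype=object)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) vertex coordinates per face."""
        return self.vertices[self.faces]

    def winding_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1)
        safe = np.where(norm > 0, norm, 1.0)
        return n / safe[:, None]

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def area_by_tag(self) -> dict[str, float]:
        areas = self.face_areas()
        out: dict[str, float] = {}
        for tag in np.unique(self.tags.astype(str)):
            out[tag] = float(areas[self.tags.astype(str) == tag].sum())
        return out

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def _weld(vertices: np.ndarray, faces: np.ndarray):
    """Merge bitwise-identical vertices so shared edges share indices."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def _parse_ascii_stl(text: str) -> TriangleMesh:
    vals = re.findall(
        r"vertex\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)", text
    )
    if not vals or len(vals) % 3:
        raise STLFormatError("malformed ASCII STL: vertex count not a multiple of 3")
    verts = np.array(vals, dtype=float)
    faces = np.arange(len(verts)).reshape(-1, 3)
    verts, faces = _weld(verts, faces)
    return TriangleMesh(vertices=verts, faces=faces)


def read_binary_stl(path) -> TriangleMesh:
    """Read an STL file (binary; ASCII is sniffed and accepted as well).

    Binary layout: 80-byte header, uint32 triangle count, then 50-byte
    records.  A declared count that disagrees with the file length raises
    :class:`STLFormatError`.  Stored normals are kept after renormalization
    when valid; degenerate stored normals are replaced by winding normals.
    """
    data = Path(path).read_bytes()
    if len(data) >= 84:
        count = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        if len(data) == 84 + 50 * count:
            records = np.frombuffer(data[84:], dtype=_STL_RECORD)
            verts = records["vertices"].reshape(-1, 3).astype(float)
            faces = np.arange(len(verts)).reshape(-1, 3)
            verts, faces = _weld(verts, faces)
            mesh = TriangleMesh(vertices=verts, faces=faces)
            stored = records["normal"].astype(float)
            norms = np.linalg.norm(stored, axis=1)
            ok = norms > 1e-6
            stored[ok] /= norms[ok, None]
            mesh.normals = np.where(ok[:, None], stored, mesh.winding_normals())
            return mesh
        if not data.lstrip()[:5].lower().startswith(b"solid"):
            raise STLFormatError(
                f"binary STL declares {count} triangles but file length "
                f"{len(data)} != {84 + 50 * count}"
            )
    if data.lstrip()[:5].lower().startswith(b"solid"):
        return _parse_ascii_stl(data.decode("ascii", errors="replace"))
    raise STLFormatError("not a recognizable binary or ASCII STL file")


def write_binary_stl(mesh: TriangleMesh, path) -> None:
    """Write a binary STL (tags are not representable in STL and are lost)."""
    records = np.zeros(mesh.n_faces, dtype=_STL_RECORD)
    records["vertices"] = mesh.triangles().astype("<f4")
    records["normal"] = mesh.winding_normals().astype("<f4")
    header = b"reconsim binary STL" + b" " * 61
    with open(path, "wb") as fh:
        fh.write(header[:80])
        fh.write(np.uint32(mesh.n_faces).tobytes())
        fh.write(records.tobytes())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ValidationReport:
    watertight: bool
    non_manifold_edges: int
    boundary_edges: int
    degenerate_faces: int
    winding_consistent: bool
    total_area: float


def validate_mesh(mesh: TriangleMesh, degenerate_area: float = 1e-12) -> ValidationReport:
    """Report-only mesh checks: edge manifoldness, winding, degeneracy, area.

    Watertight means every edge is shared by exactly two faces.
    """
    edges = np.sort(
        mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    non_manifold = int((counts > 2).sum())
    degenerate = int((mesh.face_areas() < degenerate_area).sum())
    tm = mesh.as_trimesh()
    winding = bool(tm.is_winding_consistent) if mesh.n_faces else True
    watertight = mesh.n_faces > 0 and boundary == 0 and non_manifold == 0
    return ValidationReport(
        watertight=watertight,
        non_manifold_edges=non_manifold,
        boundary_edges=boundary,
        degenerate_faces=degenerate,
        winding_consistent=winding,
        total_area=mesh.total_area(),
    )


# ---------------------------------------------------------------------------
# Synthetic operative-corridor generator
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ChannelSpec:
    """Parameters of a synthetic deep-operative-corridor mesh.

    The channel floor sits at z = 0 (plus ``z_offset_mm``); the top surface
    at z = depth.  ``segments`` controls the boundary discretization (wall
    lateral-area error from chord shortening is < 0.1 % at 128 segments);
    ``wall_band_mm`` sets the axial height of wall faces, keeping them
    roughly isotropic so the minimal-depth occlusion ordering stays sound.
    """

    cross_section: str = "circular"
    diameter_mm: float = 25.0
    axes_mm: tuple[float, float] = (42.5, 22.5)
    depth_mm: float = 50.0
    block_extent_mm: tuple[float, float] = (60.0, 60.0)
    anatomy: str = "none"
    artery_height_mm: float = 30.0
    artery_diameter_mm: float = 8.0
    seed: int = 0
    segments: int = 128
    wall_band_mm: float = 6.0
    bottom_rings: int = 5
    relief_amplitude_mm: float = 2.0
    base_thickness_mm: float = 5.0
    z_offset_mm: float = 0.0
    superellipse_exponent: float = 2.5

    def __post_init__(self):
        if self.cross_section not in ("circular", "elliptical"):
            raise MeshSpecError(f"unknown cross section {self.cross_section!r}")
        if self.anatomy not in ("none", "flat_relief", "spanning_artery", "overhang"):
            raise MeshSpecError(f"unknown anatomy {self.anatomy!r}")
        if self.depth_mm <= 0:
            raise MeshSpecError("depth_mm must be positive")
        if self.cross_section == "circular" and self.diameter_mm <= 0:
            raise MeshSpecError("diameter_mm must be positive")
        if self.cross_section == "elliptical" and min(self.axes_mm) <= 0:
            raise MeshSpecError("axes_mm must be positive")
        bx, by = self.block_extent_mm
        cw, ch = self._cross_extent()
        if bx <= cw or by <= ch:
            raise MeshSpecError("block extent must strictly exceed the channel cross section")
        if self.anatomy == "spanning_artery":
            r = 0.5 * self.artery_diameter_mm
            if not 0.0 < self.artery_height_mm - r:
                raise MeshSpecError("artery must lie above the channel floor")
            if self.artery_height_mm + r >= self.depth_mm:
                raise MeshSpecError("artery exceeds the channel depth")
        if self.segments < 8:
            raise MeshSpecError("segments must be >= 8")

    def _cross_extent(self) -> tuple[float, float]:
        if self.cross_section == "circular":
            return self.diameter_mm, self.diameter_mm
        return self.axes_mm

    def boundary(self, angles: np.ndarray) -> np.ndarray:
        """Channel cross-section boundary points at the given angles.

        Circular: a circle of the configured diameter.  Elliptical: a
        superellipse ``|x/a|^p + |y/b|^p = 1`` (p = 2.5 by default), the
        package's stated stand-in for the deformed-elliptical corridor.
        """
        c, s = np.cos(angles), np.sin(angles)
        if self.cross_section == "circular":
            r = 0.5 * self.diameter_mm
            return np.column_stack([r * c, r * s])
        a, b = 0.5 * self.axes_mm[0], 0.5 * self.axes_mm[1]
        p = self.superellipse_exponent
        x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
        y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
        return np.column_stack([x, y])


class _Builder:
    """Accumulates vertices/faces/tags with shared indices."""

    def __init__(self):
        self.vertices: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []
        self.tags: list[str] = []

    def ring(self, xy: np.ndarray, z) -> np.ndarray:
        z = np.broadcast_to(np.asarray(z, dtype=float), len(xy))
        start = len(self.vertices)
        self.vertices.extend(np.column_stack([xy, z]))
        return np.arange(start, start + len(xy))

    def point(self, p) -> int:
        self.vertices.append(np.asarray(p, dtype=float))
        return len(self.vertices) - 1

    def tri(self, a: int, b: int, c: int, tag: str):
        self.faces.append((a, b, c))
        self.tags.append(tag)

    def band(self, lower: np.ndarray, upper: np.ndarray, tag: str, flip: bool = False):
        """Two triangles per segment between two closed rings of equal size."""
        n = len(lower)
        for k in range(n):
            k1 = (k + 1) % n
            if flip:
                self.tri(lower[k], upper[k], upper[k1], tag)
                self.tri(lower[k], upper[k1], lower[k1], tag)
            else:
                self.tri(lower[k], lower[k1], upper[k1], tag)
                self.tri(lower[k], upper[k1], upper[k], tag)

    def fan(self, center: int, ring: np.ndarray, tag: str, flip: bool = False):
        n = len(ring)
        for k in range(n):
            k1 = (k + 1) % n
            if flip:
                self.tri(center, ring[k1], ring[k], tag)
            else:
                self.tri(center, ring[k], ring[k1], tag)

    def append_component(self, vertices: np.ndarray, faces: np.ndarray, tag: str):
        offset = len(self.vertices)
        self.vertices.extend(np.asarray(vertices, dtype=float))
        for f in np.asarray(faces, dtype=int) + offset:
            self.tri(*f, tag)

    def build(self) -> TriangleMesh:
        return TriangleMesh(
            vertices=np.array(self.vertices),
            faces=np.array(self.faces, dtype=np.int64),
            tags=np.array(self.tags, dtype=object),
        )


def _relief_field(spec: ChannelSpec):
    """Seeded deterministic low-amplitude height field for the channel floor.

    A sum of four random-wavevector sinusoids scaled by a radial falloff
    that vanishes at the channel wall, standing in for the small vessels and
    furrows of real bottom anatomy.
    """
    rng = np.random.default_rng(spec.seed)
    k = rng.uniform(0.2, 0.7, size=(4, 2))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=4)
    weight = rng.uniform(0.5, 1.0, size=4)
    weight = weight / weight.sum()

    def field(xy: np.ndarray, radial_frac: np.ndarray) -> np.ndarray:
        g = np.zeros(len(xy))
        for i in range(4):
            g += weight[i] * np.sin(xy @ k[i] + phase[i])
        return spec.relief_amplitude_mm * (1.0 - radial_frac**2) * g

    return field


def _artery_component(spec: ChannelSpec, embed: float = 2.5):
    """Closed capped tube spanning the channel along x at the artery height.

    The tube ends are embedded ``embed`` mm into the channel wall so the
    caps are buried in solid material (never visible); each component of the
    combined mesh remains edge-manifold.
    """
    ra = 0.5 * spec.artery_diameter_mm
    half_span = 0.5 * spec._cross_extent()[0] + embed
    z0 = spec.artery_height_mm
    na = min(32, max(16, 2 * spec.segments // 3))
    nx = min(12, max(8, spec.segments // 4))
    xs = np.linspace(-half_span, half_span, nx + 1)
    psi = 2.0 * np.pi * np.arange(na) / na
    verts = []
    for x in xs:
        verts.append(np.column_stack([
            np.full(na, x), ra * np.cos(psi), z0 + ra * np.sin(psi)
        ]))
    verts = np.vstack(verts)
    faces = []
    for s in range(nx):
        base0, base1 = s * na, (s + 1) * na
        for kk in range(na):
            k1 = (kk + 1) % na
            faces.append((base0 + kk, base0 + k1, base1 + k1))
            faces.append((base0 + kk, base1 + k1, base1 + kk))
    c_neg = len(verts)
    c_pos = len(verts) + 1
    verts = np.vstack([verts, [[-half_span, 0, z0], [half_span, 0, z0]]])
    last = nx * na
    for kk in range(na):
        k1 = (kk + 1) % na
        faces.append((c_neg, (kk + 1) % na, kk))
        faces.append((c_pos, last + kk, last + k1))
    return verts, np.array(faces, dtype=int)


def _overhang_component(spec: ChannelSpec):
    """A bulge protruding from the channel wall into the corridor."""
    cw, _ = spec._cross_extent()
    radius = min(8.0, 0.35 * 0.5 * cw)
    rho0 = spec.boundary(np.array([0.0]))[0, 0]
    z0 = min(25.0, 0.5 * spec.depth_mm)
    if z0 + radius >= spec.depth_mm:
        raise MeshSpecError("overhang exceeds the channel depth")
    sphere = trimesh.creation.icosphere(subdivisions=2, radius=radius)
    # slightly off the y = 0 symmetry plane so no camera ever sees two
    # exactly mirror-symmetric (depth-tied) bulge faces
    verts = sphere.vertices + np.array([rho0 + 0.3 * radius, 0.21 * radius, z0])
    return verts, sphere.faces


def make_channel_site(spec: ChannelSpec) -> TriangleMesh:
    """Generate a watertight operative-corridor mesh from a spec.

    Regions and tags: channel floor (+ optional relief/vessel/overhang)
    ``anatomy``; channel wall ``wall``; upper block face ``top_surface``;
    block sides and underside ``exterior``.
    """
    n = spec.segments
    depth = spec.depth_mm
    angles = 2.0 * np.pi * np.arange(n) / n
    inner = spec.boundary(angles)
    bx, by = spec.block_extent_mm
    hx, hy = 0.5 * bx, 0.5 * by
    with np.errstate(divide="ignore"):
        r_rect = np.minimum(
            np.where(np.abs(np.cos(angles)) > 1e-12, hx / np.abs(np.cos(angles)), np.inf),
            np.where(np.abs(np.sin(angles)) > 1e-12, hy / np.abs(np.sin(angles)), np.inf),
        )
    outer = np.column_stack([r_rect * np.cos(angles), r_rect * np.sin(angles)])

    relief = None
    if spec.anatomy in ("flat_relief", "spanning_artery", "overhang"):
        relief = _relief_field(spec)

    b = _Builder()
    m = spec.bottom_rings
    # channel floor: concentric rings scaled from the boundary profile
    center_z = relief(np.zeros((1, 2)), np.zeros(1))[0] if relief else 0.0
    center = b.point((0.0, 0.0, center_z))
    prev = None
    for j in range(1, m + 1):
        frac = j / m
        xy = inner * frac
        if relief is not None and j < m:
            z = relief(xy, np.full(n, frac))
        else:
            z = np.zeros(n)
        ring = b.ring(xy, z)
        if j == 1:
            b.fan(center, ring, "anatomy")
        else:
            b.band(prev, ring, "anatomy", flip=True)
        prev = ring
    floor_rim = prev

    # channel wall: axial bands, normals facing the corridor interior
    n_bands = max(1, math.ceil(depth / spec.wall_band_mm))
    lower = floor_rim
    for i in range(1, n_bands + 1):
        upper = b.ring(inner, depth * i / n_bands)
        b.band(lower, upper, "wall", flip=True)
        lower = upper
    wall_top = lower

    # top surface: annulus from the channel rim to the block boundary
    outer_top = b.ring(outer, depth)
    b.band(wall_top, outer_top, "top_surface", flip=True)

    # block exterior: sides and underside
    base_z = -spec.base_thickness_mm
    outer_bottom = b.ring(outer, base_z)
    b.band(outer_bottom, outer_top, "exterior")
    base_center = b.point((0.0, 0.0, base_z))
    b.fan(base_center, outer_bottom, "exterior", flip=True)

    if spec.anatomy == "spanning_artery":
        b.append_component(*_artery_component(spec), tag="anatomy")
    elif spec.anatomy == "overhang":
        b.append_component(*_overhang_component(spec), tag="anatomy")

    mesh = b.build()
    if spec.z_offset_mm:
        mesh.vertices = mesh.vertices + np.array([0.0, 0.0, spec.z_offset_mm])
    return mesh


def tag_top_surface(mesh: TriangleMesh, z_top: float | None = None, tol: float = 1e-6) -> np.ndarray:
    """Indices of upward-facing faces whose vertices all lie at ``z_top``.

    ``z_top`` defaults to the maximum vertex z among faces with a positive
    normal z-component.
    """
    tri_z = mesh.triangles()[:, :, 2]
    up = mesh.normals[:, 2] > 0.0
    if z_top is None:
        if not up.any():
            return np.array([], dtype=int)
        z_top = float(tri_z[up].max())
    at_top = np.all(np.abs(tri_z - z_top) <= tol, axis=1)
    return np.flatnonzero(at_top & up)
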