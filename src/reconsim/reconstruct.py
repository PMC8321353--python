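"""Combining per-camera visibility into the reconstructable subset.

A surface point counts as 3D-reconstructable when at least ``T`` cameras see
it (``T = 2`` under ideal stereo assumptions).  Per face the reconstructable
region is the union, over all T-subsets of the cameras that see the face at
all, of the intersections of the corresponding visible fragments — which is
identical, as a set, to the region covered by at least T of the per-camera
visible sets.  Two strategies compute it:

* ``enumerate`` — the literal union-over-combinations, exponential in the
  camera count (guarded by a combination cap);
* ``coverage_count`` (default) — a divide-and-conquer coverage merge:
  split the fragment list in half, compute the regions covered by >= j
  fragments (j = 1..T) in each half, and combine them with
  ``lev_k = a_k | b_k | union(a_i & b_(k-i))`` — the cascaded-union idea
  extended to coverage counts, O(M log M) overlays instead of the O(M^2)
  a sequential fold costs on many-camera rings.

Both must agree to numerical tolerance; the equivalence is enforced by test.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import geometry2d as g2
from .camera import RingSetup
from .mesh_io import TriangleMesh
from .visibility import FaceFragments, VisibilityMap, mesh_cache, visible_subset

__all__ = [
    "ReconConfig",
    "ReconstructionResult",
    "camera_lists",
    "combo_count",
    "reconstructable_face",
    "reconstructable_subset",
    "area_summary",
]


@dataclasses.dataclass
class ReconConfig:
    """Reconstructability threshold and evaluation strategy."""

    T: int = 2
    strategy: str = "coverage_count"
    enumerate_cap: int = 10**6

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.strategy not in ("enumerate", "coverage_count"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclasses.dataclass
class ReconstructionResult:
    """The reconstructable subset R with per-face fragments and bookkeeping."""

    fragments: dict[int, FaceFragments]
    camera_lists: dict[int, list[int]]
    area: float
    area_by_tag: dict[str, float]
    M: int
    T: int

    def area_excluding(self, tags=("top_surface",)) -> float:
        return self.area - sum(self.area_by_tag.get(t, 0.0) for t in tags)

    def to_mesh(self) -> TriangleMesh:
        """Triangulated fragment soup (ear-free constrained Delaunay per
        fragment polygon); boundary edges between neighbouring faces'
        fragments are not merged, so the result is not manifold."""
        verts, faces, tags = [], [], []
        for frag in self.fragments.values():
            tris = shapely.constrained_delaunay_triangles(frag.polygon)
            for tri in g2.iter_polygons(tris):
                ring2 = np.asarray(tri.exterior.coords)[:3]
                base = len(verts)
                verts.extend(g2.from_local(frag.frame, ring2))
                faces.append((base, base + 1, base + 2))
                tags.append(frag.tag)
        return TriangleMesh(
            vertices=np.array(verts, dtype=float).reshape(-1, 3),
            faces=np.array(faces, dtype=np.int64).reshape(-1, 3),
            tags=np.array(tags, dtype=object),
        )


def camera_lists(visibility_maps: list[VisibilityMap]) -> dict[int, list[int]]:
    """Per-face list of camera indices with a nonempty visible fragment."""
    out: dict[int, list[int]] = {}
    for j, vmap in enumerate(visibility_maps):
        for i in vmap.fragments:
            out.setdefault(i, []).append(j)
    return out


def combo_count(n_visible: int, T: int) -> int:
    """Number of T-subsets of the seeing cameras (0 when too few see it)."""
    if n_visible < 0 or T < 0:
        raise ValueError("arguments must be nonnegative")
    if n_visible < T:
        return 0
    return math.comb(n_visible, T)


def reconstructable_face(
    face_poly: Polygon,
    fragments_by_camera: list[FaceFragments],
    T: int,
    strategy: str = "coverage_count",
    enumerate_cap: int = 10**6,
):
    """Region of one face visible to at least T cameras, in its local frame.

    ``face_poly`` is the face's own local triangle (the coverage universe);
    ``fragments_by_camera`` holds the nonempty visible sets.  Returns a
    (possibly empty) polygon; when >= T cameras see the whole face the
    universe is returned without polygon arithmetic.
    """
    n = len(fragments_by_camera)
    if n < T:
        return Polygon()
    if sum(1 for f in fragments_by_camera if f.full) >= T:
        return face_poly
    polys = [f.polygon for f in fragments_by_camera]
    if strategy == "enumerate":
        n_combos = combo_count(n, T)
        if n_combos > enumerate_cap:
            raise ValueError(
                f"{n_combos} camera combinations exceed the cap "
                f"({enumerate_cap}); use the coverage_count strategy"
            )
        import itertools

        pieces = []
        for combo in itertools.combinations(polys, T):
            inter = combo[0]
            for p in combo[1:]:
                inter = shapely.intersection(inter, p)
                if inter.is_empty:
                    break
            if not inter.is_empty:
                pieces.append(inter)
        if not pieces:
            return Polygon()
        return g2.clean(shapely.union_all(pieces))
    return _coverage_sweep(face_poly, polys, T)


#: precision grid (mm) for the coverage sweep; far below the sliver
#: threshold yet coarse enough to merge duplicated boundary arcs exactly
_SNAP_GRID = 1e-9


def _merge_coverage(a: list, b: list, T: int) -> list:
    """Merge two coverage-level stacks.

    ``a[j-1]``/``b[j-1]`` hold the regions covered by >= j fragments of the
    respective half; a point covered >= k times in the union of both halves
    is covered >= i in one and >= k-i in the other for some split i.
    """
    out = []
    for k in range(1, T + 1):
        parts = [a[k - 1], b[k - 1]]
        parts += [
            shapely.intersection(a[i - 1], b[k - i - 1]) for i in range(1, k)
        ]
        parts = [p for p in parts if not p.is_empty]
        out.append(shapely.union_all(parts) if parts else Polygon())
    return out


def _coverage_sweep(face_poly: Polygon, polys, T: int):
    """Region covered by >= T of the polygons, by divide and conquer.

    All polygons are snapped to a 1e-9 mm precision grid first: fragments
    seen through different cameras carry near-coincident boundary arcs
    (~1e-13 mm apart) which would otherwise accumulate into pathologically
    complex intermediate unions; on the common grid they dissolve exactly.
    """
    polys = [shapely.set_precision(p, _SNAP_GRID) for p in polys]
    polys = [p for p in polys if not p.is_empty]
    if len(polys) < T:
        return Polygon()

    def rec(lo: int, hi: int) -> list:
        if hi - lo == 1:
            return [polys[lo]] + [Polygon()] * (T - 1)
        mid = (lo + hi) // 2
        return _merge_coverage(rec(lo, mid), rec(mid, hi), T)

    return g2.clean(rec(0, len(polys))[T - 1])


def reconstructable_subset(
    mesh: TriangleMesh,
    setup: RingSetup,
    config: ReconConfig | None = None,
    visibility_maps: list[VisibilityMap] | None = None,
) -> ReconstructionResult:
    """Run the per-camera pipeline for every camera and combine the results.

    ``visibility_maps`` may be supplied to reuse precomputed per-camera
    visibility (they must come from the same mesh and setup).
    """
    config = config or ReconConfig()
    if visibility_maps is None:
        visibility_maps = [visible_subset(mesh, cam) for cam in setup.cameras]
    cache = mesh_cache(mesh)
    tags = [str(t) for t in mesh.tags]
    lists = camera_lists(visibility_maps)

    fragments: dict[int, FaceFragments] = {}
    area_by_tag: dict[str, float] = {}
    total = 0.0
    for i, cams in lists.items():
        if len(cams) < config.T:
            continue
        frags = [visibility_maps[j].fragments[i] for j in cams]
        region = reconstructable_face(
            cache.local_poly(i), frags, config.T, config.strategy, config.enumerate_cap
        )
        if region.is_empty:
            continue
        full = len(region.exterior.coords) == 4 if isinstance(region, Polygon) else False
        fragments[i] = FaceFragments(
            index=i, frame=cache.frame(i), polygon=region, tag=tags[i],
            full=full and region.equals_exact(cache.local_poly(i), 0.0),
        )
        a = float(region.area)
        total += a
        area_by_tag[tags[i]] = area_by_tag.get(tags[i], 0.0) + a
    return ReconstructionResult(
        fragments=fragments,
        camera_lists=lists,
        area=total,
        area_by_tag=area_by_tag,
        M=setup.M,
        T=config.T,
    )


def area_summary(
    results_by_M: dict[int, ReconstructionResult],
    benchmark_M: int = 360,
    exclude_top: bool = False,
):
    """Normalized area table: ``|Ar|(M) = Ar(M) / Ar(benchmark_M)``.

    With ``exclude_top`` the areas of top-surface-tagged fragments are
    removed from numerator and denominator before normalizing.
    """
    import pandas as pd

    if benchmark_M not in results_by_M:
        raise ValueError(f"benchmark M={benchmark_M} missing from results")

    def _area(res: ReconstructionResult) -> float:
        return res.area_excluding() if exclude_top else res.area

    bench = _area(results_by_M[benchmark_M])
    if bench <= 0:
        raise ValueError("benchmark reconstructable area is zero")
    rows = [
        {"n": M, "Ar_mm2": _area(res), "norm": _area(res) / bench}
        for M, res in sorted(results_by_M.items())
    ]
    return pd.DataFrame(rows)
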