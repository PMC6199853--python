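"""Surface reconstruction and rigid-motion primitives.

An ordered point-cloud grid (L slices x M points per slice) is turned into a
bone surface by fitting a periodic cubic interpolating spline through each
slice, resampling every slice curve uniformly by arc length, and lofting
consecutive curves with triangle strips — the point-cloud analogue of a CAD
multisection ("loft") surface.  Plane clipping and axis rotations provide the
osteotomy primitives: cut a watertight mesh along a plane, keep one side,
close the cross-section, and rigidly reposition a fragment about an axis.

Conventions: right-handed frame, millimetres, slices roughly perpendicular
to the long axis.  Clip tolerance for on-plane classification is 1e-9 mm and
vertices exactly on the plane belong to the kept side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline, make_interp_spline

from .errors import DegenerateSliceError, EmptyResultError, SelfIntersectionWarning

PLANE_TOL = 1e-9

__all__ = [
    "Plane",
    "AxisLine",
    "PointCloudGrid",
    "TriangleMesh",
    "periodic_slice_spline",
    "slice_spline",
    "loft",
    "clip_by_plane",
    "rotate_about_axis",
    "load_mesh",
]


def _unit(v, what="vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.all(np.isfinite(v)):
        raise ValueError(f"{what} must be nonzero and finite")
    return v / n


@dataclass
class Plane:
    """Oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = _unit(self.normal, "plane normal")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(self.point.copy(), -self.normal)


@dataclass
class AxisLine:
    """Line in 3D: a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = _unit(self.direction, "axis direction")

    def distance(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.point
        return np.linalg.norm(np.cross(d, self.direction), axis=-1)


@dataclass
class PointCloudGrid:
    """L x M x 3 point grid: L slices of M corresponded points each."""

    points: np.ndarray
    slice_axis_hint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError(f"grid must be L x M x 3, got {self.points.shape}")
        L, M, _ = self.points.shape
        if L < 2 or M < 3:
            raise ValueError(f"need L >= 2 slices and M >= 3 points, got {L}x{M}")
        if self.slice_axis_hint is not None:
            self.slice_axis_hint = _unit(self.slice_axis_hint, "slice axis hint")

    @property
    def L(self) -> int:
        return self.points.shape[0]

    @property
    def M(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_flat(cls, flat: np.ndarray, grid: tuple[int, int]) -> "PointCloudGrid":
        flat = np.asarray(flat, dtype=float)
        L, M = grid
        return cls(flat.reshape(L, M, 3))


class TriangleMesh:
    """Triangle surface mesh: V x 3 vertices (mm), F x 3 oriented faces."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64))

    # -- derived quantities ------------------------------------------------

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def volume(self) -> float:
        return float(self.as_trimesh().volume)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        return int(len(tm.vertices) - len(tm.edges_unique) + len(tm.faces))

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces)

    def merged(self, other: "TriangleMesh") -> "TriangleMesh":
        faces = np.vstack([self.faces, other.faces + len(self.vertices)])
        return TriangleMesh(np.vstack([self.vertices, other.vertices]), faces)

    def save(self, path: str | Path, *, ascii_stl: bool = False) -> Path:
        path = Path(path)
        tm = self.as_trimesh()
        if path.suffix.lower() == ".stl":
            data = tm.export(file_type="stl_ascii" if ascii_stl else "stl")
        else:
            data = tm.export(file_type=path.suffix.lstrip(".").lower())
        mode = "w" if isinstance(data, str) else "wb"
        with open(path, mode) as fh:
            fh.write(data)
        return path


def load_mesh(path: str | Path) -> TriangleMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    tm.merge_vertices()
    return TriangleMesh.from_trimesh(tm)


# ---------------------------------------------------------------------------
# slice splines


def _check_slice(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateSliceError(f"slice needs M >= 3 points, got {pts.shape}")
    seg = np.diff(np.vstack([pts, pts[0]]), axis=0)
    if np.any(np.linalg.norm(seg, axis=1) < 1e-12):
        raise DegenerateSliceError("consecutive slice points coincide")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateSliceError("slice points are collinear; closed curve undefined")
    return pts


def periodic_slice_spline(slice_points: np.ndarray) -> tuple[CubicSpline, np.ndarray]:
    """Periodic cubic interpolating spline through a closed slice contour.

    Chord-length parameterised.  Returns the spline and its knot parameters
    (the input points are the spline values at those knots).
    """
    pts = _check_slice(slice_points)
    closed = np.vstack([pts, pts[0]])
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(closed, axis=0), axis=1))])
    cs = CubicSpline(t, closed, bc_type="periodic", axis=0)
    return cs, t


def _resample_arclength(cs: CubicSpline, period: float,
                        fractions: np.ndarray) -> np.ndarray:
    """Evaluate a curve at given fractions of its total arc length."""
    dense = np.linspace(0.0, period, max(2048, 16 * len(fractions)))
    pts = cs(dense)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = arc[-1]
    params = np.interp(fractions * total, arc, dense)
    return cs(params)


def slice_spline(slice_points: np.ndarray, samples: int) -> np.ndarray:
    """Closed interpolating spline through one slice, resampled uniformly
    by arc length.

    Returns ``samples`` points; the curve is closed, so the first and last
    returned points coincide (the closing point is included).
    """
    pts = _check_slice(slice_points)
    if samples < len(pts):
        raise ValueError(f"samples={samples} must be >= M={len(pts)}")
    cs, t = periodic_slice_spline(pts)
    fractions = np.linspace(0.0, 1.0, samples)
    return _resample_arclength(cs, t[-1], fractions)


# ---------------------------------------------------------------------------
# lofting


def _ring_samples(slice_points: np.ndarray, n: int) -> np.ndarray:
    """n distinct arc-length-uniform samples around one closed slice."""
    cs, t = periodic_slice_spline(slice_points)
    fractions = np.arange(n) / n
    return _resample_arclength(cs, t[-1], fractions)


def _best_shift(prev: np.ndarray, ring: np.ndarray) -> int:
    """Cyclic shift of ``ring`` minimising squared distance to ``prev``.

    Ties break to the lowest shift index, keeping lofts deterministic.
    """
    n = len(ring)
    costs = np.empty(n)
    for s in range(n):
        costs[s] = np.sum((np.roll(ring, -s, axis=0) - prev) ** 2)
    return int(np.argmin(costs))


def loft(grid: PointCloudGrid, samples_per_slice: int = 64,
         cap_ends: bool = True) -> TriangleMesh:
    """Loft a slice grid into a triangle surface.

    Every slice is resampled to ``samples_per_slice`` arc-length-uniform
    points; each ring is cyclically rotated to minimise twist against its
    predecessor; consecutive rings are joined by quad strips split into
    triangles.  With ``cap_ends`` both ends are closed by triangle fans
    around the slice centroid, giving a watertight genus-0 surface with
    V = L*n + 2 and F = 2*(L-1)*n + 2*n.
    """
    n = samples_per_slice
    if n < 3:
        raise ValueError("samples_per_slice must be >= 3")
    rings = []
    for li in range(grid.L):
        try:
            ring = _ring_samples(grid.points[li], n)
        except DegenerateSliceError as exc:
            raise DegenerateSliceError(f"slice {li}: {exc}") from exc
        if rings:
            ring = np.roll(ring, -_best_shift(rings[-1], ring), axis=0)
            gap = np.linalg.norm(ring - rings[-1], axis=1)
            if gap.max() > 4.0 * max(np.median(gap), 1e-12) + 1e-9:
                warnings.warn(
                    f"slices {li - 1} and {li} are poorly matched; the loft "
                    "may self-intersect", SelfIntersectionWarning)
        rings.append(ring)
    V = np.vstack(rings)
    faces = []
    for li in range(grid.L - 1):
        base0, base1 = li * n, (li + 1) * n
        for j in range(n):
            a, b = base0 + j, base0 + (j + 1) % n
            c, d = base1 + (j + 1) % n, base1 + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    if cap_ends:
        c0 = len(V)
        c1 = len(V) + 1
        V = np.vstack([V, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
        base = (grid.L - 1) * n
        for j in range(n):
            faces.append((c0, (j + 1) % n, j))                      # bottom fan
            faces.append((c1, base + j, base + (j + 1) % n))        # top fan
    mesh = TriangleMesh(V, np.asarray(faces, dtype=np.int64))
    # orient outward: a closed loft should enclose positive volume
    if cap_ends and mesh.volume < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# plane clipping


def _polygon_area_2d(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ear_clip(poly: np.ndarray) -> list[tuple[int, int, int]]:
    """Deterministic ear-clipping triangulation of a simple 2D polygon.

    Returns index triples into ``poly`` (CCW winding).  Only strictly convex
    ears containing no other vertex are clipped, so collinear vertices stay
    in the triangulation (they become convex as neighbours are removed) and
    every polygon vertex appears in the output — required for the cap to
    share all boundary edges with the clipped surface.
    """
    m = len(poly)
    idx = list(range(m))
    if _polygon_area_2d(poly) < 0:
        idx.reverse()
    tris: list[tuple[int, int, int]] = []

    def cross_at(seq, pos):
        a = poly[seq[pos - 1]]
        b = poly[seq[pos]]
        c = poly[seq[(pos + 1) % len(seq)]]
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    while len(idx) > 3:
        k = len(idx)
        clipped = False
        for pos in range(k):
            if cross_at(idx, pos) <= 1e-12:
                continue  # reflex or collinear vertex: not an ear yet
            i0, i1, i2 = idx[pos - 1], idx[pos], idx[(pos + 1) % k]
            a, b, c = poly[i0], poly[i1], poly[i2]
            contains = False
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = poly[j]
                d0 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d1 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d2 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d0 > -1e-12 and d1 > -1e-12 and d2 > -1e-12:
                    contains = True
                    break
            if contains:
                continue
            tris.append((i0, i1, i2))
            idx.pop(pos)
            clipped = True
            break
        if not clipped:
            # numerically stuck: clip the most convex corner regardless
            pos = max(range(k), key=lambda p_: cross_at(idx, p_))
            if cross_at(idx, pos) > 1e-12:
                tris.append((idx[pos - 1], idx[pos], idx[(pos + 1) % k]))
            idx.pop(pos)
    if len(idx) == 3 and cross_at(idx, 1) > 1e-12:
        tris.append((idx[0], idx[1], idx[2]))
    return tris


def _boundary_loops(tm: trimesh.Trimesh) -> list[list[int]]:
    """Vertex loops of boundary (single-incidence) edges."""
    edges = tm.edges_sorted
    order = np.lexsort(edges.T[::-1])
    srt = edges[order]
    uniq, counts = np.unique(srt, axis=0, return_counts=True)
    bnd = uniq[counts == 1]
    if len(bnd) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in bnd:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops = []
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxts = [v for v in adj[cur] if v != prev and v not in seen]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            loop.append(cur)
            seen.add(cur)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, ref))
    v = np.cross(normal, u)
    return u, v


def clip_by_plane(mesh: TriangleMesh, plane: Plane,
                  keep: str = "front") -> TriangleMesh:
    """Clip a mesh by a plane, keeping one side.

    ``keep="front"`` keeps the side the plane normal points toward,
    ``keep="back"`` the other.  Triangles straddling the plane are split
    along it; when the input is watertight the planar cross-section is
    triangulated closed so the output is watertight too.
    """
    if keep not in ("front", "back"):
        raise ValueError("keep must be 'front' or 'back'")
    normal = plane.normal if keep == "front" else -plane.normal
    tm_in = mesh.as_trimesh()
    was_watertight = bool(tm_in.is_watertight)
    sliced = trimesh.intersections.slice_mesh_plane(
        tm_in, plane_normal=normal, plane_origin=plane.point, cap=False)
    if len(sliced.faces) == 0:
        raise EmptyResultError("nothing lies on the kept side of the plane")
    sliced.merge_vertices()
    verts = np.asarray(sliced.vertices, dtype=float)
    faces = [np.asarray(sliced.faces, dtype=np.int64)]
    if was_watertight:
        u, v = _plane_basis(normal)
        for loop in _boundary_loops(sliced):
            pts3 = verts[loop]
            poly = np.column_stack([(pts3 - plane.point) @ u,
                                    (pts3 - plane.point) @ v])
            tris = _ear_clip(poly)
            # cap outward normal must point away from the kept half-space
            cap = np.array([[loop[a], loop[c], loop[b]] for a, b, c in tris],
                           dtype=np.int64)
            if len(cap):
                faces.append(cap)
    out = TriangleMesh(verts, np.vstack(faces))
    # drop degenerate slivers produced by the split
    areas = out.face_areas()
    good = areas > 1e-14 * max(float(areas.max()), 1.0)
    if not np.all(good):
        out = TriangleMesh(out.vertices, out.faces[good])
    return out


# ---------------------------------------------------------------------------
# rigid motions


def _rotation_matrix(direction: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit direction."""
    d = _unit(direction)
    K = np.array([[0, -d[2], d[1]],
                  [d[2], 0, -d[0]],
                  [-d[1], d[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotate_about_axis(obj, axis: AxisLine, angle: float):
    """Rigidly rotate a mesh or point array about an axis line.

    Points on the axis are fixed; pairwise distances and orientation are
    preserved.  Accepts a TriangleMesh or an (..., 3) array and returns the
    same type.
    """
    R = _rotation_matrix(axis.direction, angle)
    if isinstance(obj, TriangleMesh):
        pts = (obj.vertices - axis.point) @ R.T + axis.point
        return TriangleMesh(pts, obj.faces.copy())
    pts = np.asarray(obj, dtype=float)
    return (pts - axis.point) @ R.T + axis.point


# straight (open) spline helper shared with plate design -------------------


def open_spline_resample(points: np.ndarray, samples: int) -> np.ndarray:
    """Open interpolating cubic spline through ordered points, arc-length
    resampled; degree drops to the point count for very short inputs."""
    pts = np.asarray(points, dtype=float)
    npts = len(pts)
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    k = min(3, npts - 1)
    spl = make_interp_spline(t, pts, k=k, axis=0)
    dense = np.linspace(0.0, t[-1], max(2048, 16 * samples))
    dp = spl(dense)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(dp, axis=0), axis=1))])
    params = np.interp(np.linspace(0.0, arc[-1], samples), arc, dense)
    return spl(params)
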