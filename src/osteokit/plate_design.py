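"""Personalised plate-implant generation.

A fixation plate is derived directly from the patient's bone geometry: the
surgeon picks ordered anatomical points on the bone, an interpolating
reference line is drawn through them, the bone points inside a corridor
around that line become the plate's *contact surface* (vertex-for-vertex the
bone's own points, so the plate conforms to the periosteal surface), and the
patch is offset along its outward normals by the plate thickness and closed
into a watertight printable solid.  Screw holes are cut as polygonal prisms
through reserved blocks of the structured patch grid, which keeps the result
provably watertight without a general mesh-boolean kernel.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DuplicatePointError,
    HoleOffPlateError,
    HoleOverlapError,
    InsufficientCoverageError,
    NotWatertightError,
    SelfIntersectionError,
)
from .geometry3d import TriangleMesh, open_spline_resample

__all__ = [
    "HoleSpec",
    "PlateSpec",
    "ContactPatch",
    "PlateModel",
    "build_reference_line",
    "extract_contact_patch",
    "solidify",
    "add_screw_holes",
    "export_plate",
    "design_plate",
]


@dataclass
class HoleSpec:
    count: int
    diameter: float
    placement: list[float]  # arc-length fractions along the reference line

    def __post_init__(self) -> None:
        self.placement = [float(f) for f in self.placement]
        if self.count != len(self.placement):
            raise ValueError("hole count disagrees with placement list")
        if self.diameter <= 0:
            raise ValueError("hole diameter must be > 0")
        if any(not (0.0 <= f <= 1.0) for f in self.placement):
            raise ValueError("hole placement fractions must lie in [0, 1]")


@dataclass
class PlateSpec:
    """Designer/surgeon input for one plate.

    The corridor half-width (how far from the reference line bone points are
    recruited into the contact surface) has no default on purpose: it is a
    clinical choice that must be stated explicitly.
    """

    reference_point_ids: list[str]
    corridor_half_width: float
    thickness: float
    hole_spec: HoleSpec | None = None
    plate_label: str = "plate"
    u_cluster_gap: float | None = None  # mm gap separating along-line levels

    def __post_init__(self) -> None:
        if len(self.reference_point_ids) < 2:
            raise ValueError("need at least 2 reference points")
        if self.corridor_half_width <= 0:
            raise ValueError("corridor_half_width must be > 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if (self.hole_spec is not None
                and self.hole_spec.diameter >= 2 * self.corridor_half_width):
            raise ValueError("hole diameter must be < corridor width")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlateSpec":
        from .errors import ConfigError

        data = json.loads(Path(path).read_text())
        for req in ("reference_point_ids", "corridor_half_width", "thickness"):
            if req not in data:
                raise ConfigError(f"plate spec is missing required field {req!r}")
        hole = data.get("hole_spec")
        return cls(
            reference_point_ids=list(data["reference_point_ids"]),
            corridor_half_width=float(data["corridor_half_width"]),
            thickness=float(data["thickness"]),
            hole_spec=HoleSpec(**hole) if hole else None,
            plate_label=data.get("plate_label", "plate"),
            u_cluster_gap=data.get("u_cluster_gap"),
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "reference_point_ids": self.reference_point_ids,
            "corridor_half_width": self.corridor_half_width,
            "thickness": self.thickness,
            "hole_spec": None if self.hole_spec is None else {
                "count": self.hole_spec.count,
                "diameter": self.hole_spec.diameter,
                "placement": self.hole_spec.placement,
            },
            "plate_label": self.plate_label,
            "u_cluster_gap": self.u_cluster_gap,
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")


# ---------------------------------------------------------------------------
# reference line


def build_reference_line(points: np.ndarray,
                         samples_per_point: int = 10) -> np.ndarray:
    """Open interpolating cubic spline polyline through ordered points.

    The surgeon's selection order is authoritative; the curve passes through
    every input point and is resampled uniformly by arc length.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need an ordered list of >= 2 points in 3D")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-12:
        raise DuplicatePointError("reference points must be distinct")
    samples = max(2, samples_per_point * len(pts))
    return open_spline_resample(pts, samples)


def _project_to_polyline(points: np.ndarray, line: np.ndarray):
    """Closest-point projection of each point onto a polyline.

    Returns (u, closest, tangent, dist): arc-length coordinate, foot point,
    unit tangent of the host segment, and distance.
    """
    P = np.asarray(points, dtype=float)
    A = line[:-1]                      # segment starts
    D = line[1:] - line[:-1]
    seg_len = np.linalg.norm(D, axis=1)
    ok = seg_len > 1e-15
    A, D, seg_len = A[ok], D[ok], seg_len[ok]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # t in [0,1] per (point, segment)
    AP = P[:, None, :] - A[None, :, :]
    t = np.clip(np.einsum("psd,sd->ps", AP, D) / (seg_len ** 2), 0.0, 1.0)
    C = A[None, :, :] + t[..., None] * D[None, :, :]
    d2 = np.sum((P[:, None, :] - C) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(P))
    closest = C[rows, best]
    u = cum[best] + t[rows, best] * seg_len[best]
    tangent = D[best] / seg_len[best, None]
    dist = np.sqrt(d2[rows, best])
    return u, closest, tangent, dist


# ---------------------------------------------------------------------------
# contact patch


@dataclass
class ContactPatch:
    """Structured u x v grid of bone points around the reference line.

    ``grid_points[i, j]`` is a bone point; ``point_indices`` maps back into
    the supplied bone point array (contact fidelity: the patch never
    resamples the bone surface).
    """

    grid_points: np.ndarray          # nu x nv x 3
    point_indices: np.ndarray        # nu x nv, into the source bone points
    mesh: TriangleMesh
    u_levels: np.ndarray
    line: np.ndarray = field(repr=False, default=None)
    outward_flipped: bool = False

    @property
    def nu(self) -> int:
        return self.grid_points.shape[0]

    @property
    def nv(self) -> int:
        return self.grid_points.shape[1]


def _grid_faces(nu: int, nv: int, flip: bool) -> np.ndarray:
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = i * nv + j + 1
            c = (i + 1) * nv + j + 1
            d = (i + 1) * nv + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    f = np.asarray(faces, dtype=np.int64)
    return f[:, ::-1] if flip else f


def extract_contact_patch(bone_points: np.ndarray, line: np.ndarray,
                          half_width: float, *,
                          u_decimals: int = 6,
                          u_cluster_gap: float | None = None,
                          outward_hint: np.ndarray | None = None) -> ContactPatch:
    """Select bone points within ``half_width`` of the reference line and
    organise them into a structured patch.

    Points are keyed by arc-length projection u and ordered within each
    u-level by signed lateral offset v.  Levels are identified either by
    rounding u to ``u_decimals`` decimals (corresponded grids share exact u
    values) or, when ``u_cluster_gap`` is given, by splitting the sorted u
    values at gaps larger than that many mm — the robust choice when the
    reference line is curved.  ``outward_hint`` (e.g. the bone centroid)
    orients the patch normals away from the bone interior.
    """
    pts = np.asarray(bone_points, dtype=float)
    u, closest, tangent, dist = _project_to_polyline(pts, line)
    sel = np.flatnonzero(dist <= half_width + 1e-12)
    if len(sel) < 6:
        raise InsufficientCoverageError(
            f"only {len(sel)} bone points inside the corridor; widen it")
    off = pts[sel] - closest[sel]
    tan = tangent[sel]
    # across-line direction: tangent x mean radial offset; falls back to a
    # fixed perpendicular when the corridor straddles the line symmetrically
    tmean = tan.mean(axis=0)
    ref = np.cross(tmean, off.mean(axis=0))
    if np.linalg.norm(ref) < 1e-9:
        ref = np.cross(tmean, [0.0, 0.0, 1.0])
        if np.linalg.norm(ref) < 1e-9:
            ref = np.cross(tmean, [0.0, 1.0, 0.0])
    lat = ref[None, :] - (tan @ ref)[:, None] * tan
    norms = np.linalg.norm(lat, axis=1)
    norms[norms < 1e-15] = 1.0
    lat /= norms[:, None]
    v = np.einsum("pd,pd->p", off, lat)

    usel = u[sel]
    if u_cluster_gap is not None:
        order_u = np.argsort(usel, kind="stable")
        labels = np.empty(len(usel), dtype=int)
        lab = 0
        prev = None
        for k in order_u:
            if prev is not None and usel[k] - prev > u_cluster_gap:
                lab += 1
            labels[k] = lab
            prev = usel[k]
        uniq = np.array([usel[labels == g].mean() for g in range(lab + 1)])
        groups = [np.flatnonzero(labels == g) for g in range(lab + 1)]
    else:
        levels = np.round(usel, u_decimals)
        uniq = np.unique(levels)
        groups = [np.flatnonzero(levels == lev) for lev in uniq]
    if len(uniq) < 3:
        raise InsufficientCoverageError(
            f"corridor spans only {len(uniq)} u-levels (need >= 3)")
    rows = []
    counts = set()
    for members in groups:
        order = members[np.argsort(v[members], kind="stable")]
        rows.append(sel[order])
        counts.add(len(order))
    if len(counts) != 1:
        raise InsufficientCoverageError(
            "corridor selection is not a structured grid (unequal points per "
            f"u-level: {sorted(counts)}); adjust half_width or u_decimals")
    nv = counts.pop()
    if nv < 2:
        raise InsufficientCoverageError("corridor spans only 1 v-level (need >= 2)")
    idx = np.vstack(rows)                       # nu x nv
    grid = pts[idx]                             # nu x nv x 3

    flip = False
    if outward_hint is not None:
        faces = _grid_faces(len(uniq), nv, flip=False)
        verts = grid.reshape(-1, 3)
        fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                      verts[faces[:, 2]] - verts[faces[:, 0]])
        outward = grid.reshape(-1, 3).mean(axis=0) - np.asarray(outward_hint, float)
        if fn.sum(axis=0) @ outward < 0:
            flip = True
    mesh = TriangleMesh(grid.reshape(-1, 3),
                        _grid_faces(len(uniq), nv, flip))
    return ContactPatch(grid_points=grid, point_indices=idx, mesh=mesh,
                        u_levels=uniq, line=np.asarray(line, float),
                        outward_flipped=flip)


# ---------------------------------------------------------------------------
# solidification


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Angle-weighted average of incident face normals, unit length."""
    vn = np.zeros_like(vertices)
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fl = np.linalg.norm(fn, axis=1)
    fl[fl < 1e-30] = 1.0
    fn = fn / fl[:, None]
    for corner in range(3):
        a = tri[:, (corner + 1) % 3] - tri[:, corner]
        b = tri[:, (corner + 2) % 3] - tri[:, corner]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip(np.einsum("fd,fd->f", a, b) / (na * nb), -1.0, 1.0)
        ang = np.arccos(cosang)
        np.add.at(vn, faces[:, corner], fn * ang[:, None])
    ln = np.linalg.norm(vn, axis=1)
    if np.any(ln < 1e-15):
        raise SelfIntersectionError("degenerate vertex normal on the patch")
    return vn / ln[:, None]


def _patch_normals(patch: ContactPatch) -> np.ndarray:
    """Outward unit normals on the patch grid, shape nu x nv x 3."""
    verts = patch.grid_points.reshape(-1, 3)
    vn = _vertex_normals(verts, patch.mesh.faces)
    return vn.reshape(patch.nu, patch.nv, 3)


def _boundary_loop(nu: int, nv: int) -> list[int]:
    """Perimeter node indices of an nu x nv grid, as one cycle."""
    loop = [0 * nv + j for j in range(nv)]
    loop += [i * nv + (nv - 1) for i in range(1, nu)]
    loop += [(nu - 1) * nv + j for j in range(nv - 2, -1, -1)]
    loop += [i * nv + 0 for i in range(nu - 2, 0, -1)]
    return loop


def _stitch_rings(outer_idx: Sequence[int], outer_ang: np.ndarray,
                  inner_idx: Sequence[int], inner_ang: np.ndarray,
                  param_xy: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the annulus between two closed loops sorted by angle.

    A two-pointer merge over unwrapped angles; each emitted triangle is
    reordered CCW in the 2D parameter plane.
    """
    oo = np.argsort(outer_ang, kind="stable")
    ii = np.argsort(inner_ang, kind="stable")
    O = [outer_idx[k] for k in oo]
    I = [inner_idx[k] for k in ii]
    ao = np.concatenate([outer_ang[oo], [outer_ang[oo][0] + 2 * math.pi]])
    ai = np.concatenate([inner_ang[ii], [inner_ang[ii][0] + 2 * math.pi]])
    a, b = len(O), len(I)
    tris: list[tuple[int, int, int]] = []

    def ccw(t):
        p0, p1, p2 = (param_xy[v] for v in t)
        s = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
        return t if s >= 0 else (t[0], t[2], t[1])

    i = j = 0
    while i < a or j < b:
        if j >= b or (i < a and ao[i + 1] <= ai[j + 1]):
            tris.append(ccw((O[i % a], O[(i + 1) % a], I[j % b])))
            i += 1
        else:
            tris.append(ccw((O[i % a], I[(j + 1) % b], I[j % b])))
            j += 1
    return tris


def _build_solid(patch: ContactPatch, thickness: float,
                 holes: HoleSpec | None = None,
                 hole_sides: int = 64) -> TriangleMesh:
    nu, nv = patch.nu, patch.nv
    C = patch.grid_points                        # contact grid
    N = _patch_normals(patch)
    O = C + thickness * N                        # offset (outer) grid

    # local inversion check: offsetting must not flip any face
    cf = patch.mesh.faces
    cv = C.reshape(-1, 3)
    ov = O.reshape(-1, 3)
    n_c = np.cross(cv[cf[:, 1]] - cv[cf[:, 0]], cv[cf[:, 2]] - cv[cf[:, 0]])
    n_o = np.cross(ov[cf[:, 1]] - ov[cf[:, 0]], ov[cf[:, 2]] - ov[cf[:, 0]])
    if np.any(np.einsum("fd,fd->f", n_c, n_o) <= 0):
        raise SelfIntersectionError(
            f"thickness {thickness} mm exceeds the local curvature radius of "
            "the contact patch")

    # hole blocks in grid-index space
    blocks: list[tuple[int, int, int, int]] = []   # i0, i1, j0, j1 (node ranges)
    rings: list[dict] = []
    if holes is not None and holes.count > 0:
        u0, u1 = patch.u_levels[0], patch.u_levels[-1]
        for frac in holes.placement:
            u_t = u0 + frac * (u1 - u0)
            ic = int(np.argmin(np.abs(patch.u_levels - u_t)))
            jc = int(round((nv - 1) / 2))
            du = np.linalg.norm(C[min(ic + 1, nu - 1), jc]
                                - C[max(ic - 1, 0), jc]) / 2
            dv = np.linalg.norm(C[ic, min(jc + 1, nv - 1)]
                                - C[ic, max(jc - 1, 0)]) / 2
            r = holes.diameter / 2
            hi = int(math.ceil(r / max(du, 1e-12))) + 1
            hj = int(math.ceil(r / max(dv, 1e-12))) + 1
            i0, i1 = ic - hi, ic + hi
            j0, j1 = jc - hj, jc + hj
            if i0 < 1 or i1 > nu - 2 or j0 < 1 or j1 > nv - 2:
                raise HoleOffPlateError(
                    f"hole at fraction {frac} (grid node {ic},{jc}) does not "
                    "fit inside the plate interior")
            for bi0, bi1, bj0, bj1 in blocks:
                if i0 <= bi1 and bi0 <= i1 and j0 <= bj1 and bj0 <= j1:
                    raise HoleOverlapError("screw-hole footprints overlap")
            blocks.append((i0, i1, j0, j1))
            rings.append({"center": (ic, jc), "block": (i0, i1, j0, j1),
                          "du": du, "dv": dv, "r": r})

    def in_block_cell(i: int, j: int) -> bool:
        return any(i0 <= i < i1 and j0 <= j < j1
                   for i0, i1, j0, j1 in blocks)

    node = lambda i, j: i * nv + j
    VN = nu * nv
    verts = [cv, ov]
    extra_off = 2 * VN
    top_faces: list[tuple[int, int, int]] = []    # indices into contact layer
    for i in range(nu - 1):
        for j in range(nv - 1):
            if in_block_cell(i, j):
                continue
            aa, bb = node(i, j), node(i, j + 1)
            cc, dd = node(i + 1, j + 1), node(i + 1, j)
            # CCW in the (i, j) parameter plane, matching the hole annulus
            top_faces.append((aa, cc, bb))
            top_faces.append((aa, dd, cc))

    hole_wall_quads: list[tuple[int, int]] = []   # (contact ring idx, ring size)
    for ring in rings:
        ic, jc = ring["center"]
        i0, i1, j0, j1 = ring["block"]
        du, dv, r = ring["du"], ring["dv"], ring["r"]
        # block perimeter loop (CCW in (i, j) parameter plane)
        per = [node(i, j0) for i in range(i0, i1)]
        per += [node(i1, j) for j in range(j0, j1)]
        per += [node(i, j1) for i in range(i1, i0, -1)]
        per += [node(i0, j) for j in range(j1, j0, -1)]
        per_ij = np.array([(k // nv, k % nv) for k in per], dtype=float)
        per_ang = np.arctan2(per_ij[:, 1] - jc, per_ij[:, 0] - ic)
        # hole ring in parameter space, bilinear-mapped to both surfaces
        theta = 2 * math.pi * np.arange(hole_sides) / hole_sides
        pi_ = ic + (r / du) * np.cos(theta)
        pj_ = jc + (r / dv) * np.sin(theta)

        def bilerp(Gr, pi, pj):
            i_f = np.clip(np.floor(pi).astype(int), 0, nu - 2)
            j_f = np.clip(np.floor(pj).astype(int), 0, nv - 2)
            fi = pi - i_f
            fj = pj - j_f
            return ((1 - fi)[:, None] * (1 - fj)[:, None] * Gr[i_f, j_f]
                    + fi[:, None] * (1 - fj)[:, None] * Gr[i_f + 1, j_f]
                    + (1 - fi)[:, None] * fj[:, None] * Gr[i_f, j_f + 1]
                    + fi[:, None] * fj[:, None] * Gr[i_f + 1, j_f + 1])

        ring_c = bilerp(C, pi_, pj_)
        ring_n = bilerp(N, pi_, pj_)
        ring_n /= np.linalg.norm(ring_n, axis=1)[:, None]
        ring_o = ring_c + thickness * ring_n
        rc_idx = list(range(extra_off, extra_off + hole_sides))
        extra_off += hole_sides
        ro_idx = list(range(extra_off, extra_off + hole_sides))
        extra_off += hole_sides
        verts.append(ring_c)
        verts.append(ring_o)
        ring_ang = np.arctan2(pj_ - jc, pi_ - ic)
        # parameter-plane coordinates for CCW orientation decisions
        all_param = {k: (k // nv, k % nv) for k in per}
        for t, kk in enumerate(rc_idx):
            all_param[kk] = (pi_[t], pj_[t])
        annulus = _stitch_rings(per, per_ang, rc_idx, ring_ang, all_param)
        top_faces.extend(annulus)
        hole_wall_quads.append((rc_idx[0], hole_sides))
        ring["rc_idx"] = rc_idx
        ring["ro_idx"] = ro_idx

    def lift(face, to_outer: bool):
        """Map a contact-layer face index set to the outer layer."""
        out = []
        for k in face:
            if k < VN:
                out.append(k + VN if to_outer else k)
            else:
                out.append(k + hole_sides if to_outer else k)
        return tuple(out)

    faces: list[tuple[int, int, int]] = []
    for f in top_faces:
        faces.append(lift(f, True))                      # outer surface, CCW
        faces.append(tuple(reversed(lift(f, False))))    # contact surface
    # perimeter side walls (loop reversed so walls oppose the contact faces)
    loop = _boundary_loop(nu, nv)[::-1]
    for a, b in zip(loop, loop[1:] + loop[:1]):
        faces.append((a, b, b + VN))
        faces.append((a, b + VN, a + VN))
    # hole walls
    for ring in rings:
        rc, ro = ring["rc_idx"], ring["ro_idx"]
        n = len(rc)
        for t in range(n):
            a, b = rc[t], rc[(t + 1) % n]
            a2, b2 = ro[t], ro[(t + 1) % n]
            faces.append((b, a, a2))
            faces.append((b, a2, b2))
    mesh = TriangleMesh(np.vstack(verts), np.asarray(faces, dtype=np.int64))
    tm = mesh.as_trimesh()
    tm.remove_unreferenced_vertices()
    mesh = TriangleMesh.from_trimesh(tm)
    if mesh.volume < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def solidify(patch: ContactPatch, thickness: float) -> TriangleMesh:
    """Offset the contact patch by ``thickness`` along outward per-vertex
    normals (angle-weighted) and close it into a watertight solid.

    Every outer vertex sits at Euclidean distance exactly ``thickness`` from
    its contact counterpart.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    return _build_solid(patch, thickness, holes=None)


@dataclass
class PlateModel:
    contact_surface: TriangleMesh
    solid: TriangleMesh
    spec: PlateSpec
    source_bone_ref: str = ""
    patch: ContactPatch | None = field(default=None, repr=False)


def add_screw_holes(plate: PlateModel, hole_spec: HoleSpec | None = None,
                    hole_sides: int = 64) -> PlateModel:
    """Cut cylindrical (regular-polygon prism) through-holes along the local
    surface normals.  Zero holes is the identity."""
    spec = hole_spec if hole_spec is not None else plate.spec.hole_spec
    if spec is None or spec.count == 0:
        return plate
    if plate.patch is None:
        raise ValueError("plate has no structured patch attached")
    solid = _build_solid(plate.patch, plate.spec.thickness, holes=spec,
                         hole_sides=hole_sides)
    return PlateModel(contact_surface=plate.contact_surface, solid=solid,
                      spec=plate.spec, source_bone_ref=plate.source_bone_ref,
                      patch=plate.patch)


def design_plate(bone_points: np.ndarray, landmarks: Mapping[str, np.ndarray],
                 spec: PlateSpec, *, bone_ref: str = "",
                 with_holes: bool = True) -> PlateModel:
    """End-to-end plate construction from bone points and named landmarks."""
    ref_pts = np.array([landmarks[i] for i in spec.reference_point_ids],
                       dtype=float)
    line = build_reference_line(ref_pts)
    centroid = np.asarray(bone_points, dtype=float).mean(axis=0)
    patch = extract_contact_patch(bone_points, line, spec.corridor_half_width,
                                  u_cluster_gap=spec.u_cluster_gap,
                                  outward_hint=centroid)
    solid = solidify(patch, spec.thickness)
    plate = PlateModel(contact_surface=patch.mesh, solid=solid, spec=spec,
                       source_bone_ref=bone_ref, patch=patch)
    if with_holes and spec.hole_spec is not None:
        plate = add_screw_holes(plate)
    return plate


def export_plate(plate: PlateModel, path: str | Path,
                 file_format: str = "stl") -> Path:
    """Write the plate solid (binary/ASCII STL or PLY) plus a JSON manifest
    recording the spec, source-bone hash and mesh statistics."""
    if not plate.solid.is_watertight:
        raise NotWatertightError("plate solid is not watertight; refusing export")
    path = Path(path)
    if file_format == "stl":
        plate.solid.save(path)
    elif file_format == "stl_ascii":
        plate.solid.save(path, ascii_stl=True)
    elif file_format == "ply":
        plate.solid.save(path.with_suffix(".ply"))
        path = path.with_suffix(".ply")
    else:
        raise ValueError(f"unknown plate format {file_format!r}")
    tm = plate.solid.as_trimesh()
    manifest = {
        "plate_label": plate.spec.plate_label,
        "source_bone_ref": plate.source_bone_ref,
        "thickness_mm": plate.spec.thickness,
        "corridor_half_width_mm": plate.spec.corridor_half_width,
        "reference_point_ids": plate.spec.reference_point_ids,
        "holes": None if plate.spec.hole_spec is None else {
            "count": plate.spec.hole_spec.count,
            "diameter_mm": plate.spec.hole_spec.diameter,
            "placement": plate.spec.hole_spec.placement,
        },
        "mesh": {
            "vertices": int(len(tm.vertices)),
            "faces": int(len(tm.faces)),
            "area_mm2": float(tm.area),
            "volume_mm3": float(tm.volume),
            "bounds_mm": np.asarray(tm.bounds).tolist(),
            "watertight": bool(tm.is_watertight),
        },
        "file_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n")
    return path
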