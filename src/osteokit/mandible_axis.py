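"""Temporomandibular rotational-axis reconstruction and osteotomy planning.

When the condylar region is missing from a 3D scan, the hinge axis of the
temporomandibular joint can still be located from a lateral X-ray: menton
(ME, lowest point of the mandibular symphysis) and gonion (GO, most inferior
point of the mandibular angle) define the mandibular line, the incisal edges
and occluding cusp tips define the occlusion line, and the surgeon marks the
axis point on the image.  Perpendiculars dropped from the axis point to both
lines give two foot distances (scaled from pixels to mm by an etalon of
known length).  Transferring those distances to the patient's 3D occlusion
and mandibular *planes* and erecting perpendicular planes at them, the axis
is the intersection line of the two erected planes.

A single lateral view cannot constrain the axis direction, which is
therefore taken perpendicular to the sagittal plane of the anatomical frame
(i.e. medio-lateral) — the hinge-axis interpretation.

2D image input uses the pixel convention (origin top-left, y downward);
coordinates are converted internally to y-up millimetres after etalon
scaling, so all reported distances are rigid-motion invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import (
    DegenerateLineError,
    MissingLandmarkError,
    ParallelPlanesError,
    ZeroLengthError,
)
from .geometry3d import AxisLine, Plane, TriangleMesh, clip_by_plane, rotate_about_axis
from .errors import EmptyResultError

OCCLUSION_PREFIX = "occ"

__all__ = [
    "Landmark2D",
    "CephalometricConstruction2D",
    "AnatomicalFrame3D",
    "etalon_scale",
    "construct_2d",
    "reconstruct_axis",
    "plan_osteotomy",
    "load_landmark_scene",
    "load_frame_json",
    "axis_to_json",
]


@dataclass
class Landmark2D:
    """A named point on the X-ray image, in pixels."""

    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise ValueError("2D landmark needs exactly 2 pixel coordinates")


@dataclass
class CephalometricConstruction2D:
    """Mandibular/occlusion lines and axis-point perpendiculars, in mm.

    ``dist_mandibular``: signed distance from ME to the perpendicular foot,
    along the ME→GO direction.  ``dist_occlusion``: signed distance from the
    most-anterior occlusion landmark (projected onto the occlusion line) to
    its foot, along the posterior direction.  ``perp_*`` are the signed
    perpendicular lengths from each line to the axis point.
    """

    mandibular_point: np.ndarray      # ME (mm, y-up)
    mandibular_dir: np.ndarray        # unit, ME -> GO
    occlusion_point: np.ndarray       # most-anterior occlusion landmark on line
    occlusion_dir: np.ndarray         # unit, oriented posteriorly
    rotation_point: np.ndarray
    foot_mandibular: np.ndarray
    foot_occlusion: np.ndarray
    dist_mandibular: float
    dist_occlusion: float
    perp_mandibular: float
    perp_occlusion: float


@dataclass
class AnatomicalFrame3D:
    """Patient 3D frame: occlusion and mandibular planes plus landmarks (mm).

    ``occlusion_ref`` is the 3D position of the most-anterior occlusion
    landmark; when omitted, the projection of ME onto the occlusion plane is
    used as the occlusion reference.
    """

    occlusion_plane: Plane
    mandibular_plane: Plane
    ME: np.ndarray
    GO_left: np.ndarray
    GO_right: np.ndarray
    occlusion_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ME = np.asarray(self.ME, dtype=float)
        self.GO_left = np.asarray(self.GO_left, dtype=float)
        self.GO_right = np.asarray(self.GO_right, dtype=float)
        if self.occlusion_ref is not None:
            self.occlusion_ref = np.asarray(self.occlusion_ref, dtype=float)
        cx = np.cross(self.occlusion_plane.normal, self.mandibular_plane.normal)
        if np.linalg.norm(cx) < 1e-9:
            raise ParallelPlanesError(
                "occlusion and mandibular planes are parallel")


def etalon_scale(etalon_px: float, etalon_mm: float) -> float:
    """mm-per-pixel factor from an etalon of known physical length."""
    if etalon_px <= 0 or etalon_mm <= 0:
        raise ZeroLengthError("etalon lengths must be strictly positive")
    return etalon_mm / etalon_px


def _px_to_mm(p: np.ndarray, scale: float) -> np.ndarray:
    # pixel y points down; flip to a y-up mm frame
    return np.array([p[0] * scale, -p[1] * scale])


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares (principal-axis) line fit; rigid-motion invariant."""
    c = points.mean(axis=0)
    centered = points - c
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] < 1e-12:
        raise DegenerateLineError("occlusion landmarks coincide")
    return c, vt[0]


def construct_2d(landmarks: Mapping[str, np.ndarray] | list[Landmark2D],
                 scale: float) -> CephalometricConstruction2D:
    """Build the 2D cephalometric construction from named pixel landmarks.

    Requires ``ME``, ``GO``, ``rotation_point`` and at least two occlusion
    landmarks (names starting with ``occ``).  All outputs are in mm, y-up.
    """
    if not isinstance(landmarks, Mapping):
        landmarks = {lm.name: lm.position for lm in landmarks}
    for req in ("ME", "GO", "rotation_point"):
        if req not in landmarks:
            raise MissingLandmarkError(f"landmark {req!r} is required")
    occ_names = sorted(n for n in landmarks if n.startswith(OCCLUSION_PREFIX))
    if len(occ_names) < 2:
        raise MissingLandmarkError(
            "need at least two occlusion landmarks (names starting 'occ')")
    ME = _px_to_mm(np.asarray(landmarks["ME"], float), scale)
    GO = _px_to_mm(np.asarray(landmarks["GO"], float), scale)
    R = _px_to_mm(np.asarray(landmarks["rotation_point"], float), scale)
    occ = np.array([_px_to_mm(np.asarray(landmarks[n], float), scale)
                    for n in occ_names])

    if np.linalg.norm(GO - ME) < 1e-9:
        raise DegenerateLineError("ME and GO coincide")
    d_m = (GO - ME) / np.linalg.norm(GO - ME)

    c_o, d_o = _tls_line(occ)
    anterior = (ME - GO) / np.linalg.norm(ME - GO)
    if d_o @ anterior > 0:          # orient posteriorly
        d_o = -d_o
    occ_ref = occ[np.argmax(occ @ anterior)]
    occ_ref_on = c_o + ((occ_ref - c_o) @ d_o) * d_o

    def left_normal(d):
        return np.array([-d[1], d[0]])

    foot_m = ME + ((R - ME) @ d_m) * d_m
    foot_o = c_o + ((R - c_o) @ d_o) * d_o
    return CephalometricConstruction2D(
        mandibular_point=ME, mandibular_dir=d_m,
        occlusion_point=occ_ref_on, occlusion_dir=d_o,
        rotation_point=R, foot_mandibular=foot_m, foot_occlusion=foot_o,
        dist_mandibular=float((foot_m - ME) @ d_m),
        dist_occlusion=float((foot_o - occ_ref_on) @ d_o),
        perp_mandibular=float((R - foot_m) @ left_normal(d_m)),
        perp_occlusion=float((R - foot_o) @ left_normal(d_o)),
    )


def _project_to_plane(p: np.ndarray, plane: Plane) -> np.ndarray:
    return p - ((p - plane.point) @ plane.normal) * plane.normal


def reconstruct_axis(frame: AnatomicalFrame3D,
                     construction: CephalometricConstruction2D) -> AxisLine:
    """Transfer the 2D foot distances to the 3D frame and intersect the two
    erected perpendicular planes into the rotational axis line.

    The erected planes are perpendicular to the occlusion (resp. mandibular)
    plane, placed at the measured distance along the in-plane sagittal
    direction from the occlusion reference (resp. ME).  Their intersection —
    a medio-lateral line — is the temporomandibular hinge axis.
    """
    n_o = frame.occlusion_plane.normal
    n_m = frame.mandibular_plane.normal
    sag = np.cross(n_o, n_m)
    if np.linalg.norm(sag) < 1e-9:
        raise ParallelPlanesError("occlusion and mandibular planes are parallel")
    n_sag = sag / np.linalg.norm(sag)

    GO_mid = 0.5 * (frame.GO_left + frame.GO_right)
    anterior = frame.ME - GO_mid
    anterior = anterior / np.linalg.norm(anterior)

    d_m3 = np.cross(n_m, n_sag)
    d_m3 /= np.linalg.norm(d_m3)
    if d_m3 @ (GO_mid - frame.ME) < 0:       # orient ME -> GO
        d_m3 = -d_m3
    d_o3 = np.cross(n_o, n_sag)
    d_o3 /= np.linalg.norm(d_o3)
    if d_o3 @ anterior > 0:                  # orient posteriorly
        d_o3 = -d_o3

    me_on = _project_to_plane(frame.ME, frame.mandibular_plane)
    occ_ref = (frame.occlusion_ref if frame.occlusion_ref is not None
               else frame.ME)
    occ_on = _project_to_plane(occ_ref, frame.occlusion_plane)

    q_m = me_on + construction.dist_mandibular * d_m3
    q_o = occ_on + construction.dist_occlusion * d_o3

    # intersection of the two erected planes (normals d_m3 and d_o3)
    A = np.vstack([d_m3, d_o3])
    b = np.array([d_m3 @ q_m, d_o3 @ q_o]) - A @ GO_mid
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    point = GO_mid + delta
    direction = np.cross(d_o3, d_m3)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        raise ParallelPlanesError("erected perpendicular planes are parallel")
    return AxisLine(point=point, direction=direction / nrm)


def plan_osteotomy(mandible: TriangleMesh, cut_left: Plane, cut_right: Plane,
                   axis: AxisLine, angle: float) -> dict[str, TriangleMesh]:
    """Cut the mandible along both cut planes and rotate the freed segment
    about the joint axis.

    Both plane normals must point toward the segment to reposition (the
    anterior, tooth-bearing part, with cuts in front of the seventh tooth on
    each side).  Returns watertight fragments; the combined fragment volume
    equals the input volume, and repositioning is a rigid motion, so every
    fragment volume is preserved.
    """
    moved = clip_by_plane(clip_by_plane(mandible, cut_left, keep="front"),
                          cut_right, keep="front")
    fixed_parts = []
    try:
        fixed_parts.append(clip_by_plane(mandible, cut_left, keep="back"))
    except EmptyResultError:
        pass
    try:
        front = clip_by_plane(mandible, cut_left, keep="front")
        fixed_parts.append(clip_by_plane(front, cut_right, keep="back"))
    except EmptyResultError:
        pass
    if not fixed_parts:
        raise EmptyResultError("cut planes do not intersect the mandible")
    fixed = fixed_parts[0]
    for part in fixed_parts[1:]:
        fixed = fixed.merged(part)
    repositioned = rotate_about_axis(moved, axis, angle)
    return {
        "fixed_part": fixed,
        "repositioned_part": repositioned,
        "moved_part_original": moved,
    }


# ---------------------------------------------------------------------------
# JSON interfaces


def load_landmark_scene(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read a 2D landmark scene: ``{"landmarks": {name: [x, y]}, "etalon":
    {"px": ..., "mm": ...}}``.  Returns (landmarks, mm-per-px scale)."""
    data = json.loads(Path(path).read_text())
    lms = {k: np.asarray(v, dtype=float) for k, v in data["landmarks"].items()}
    et = data["etalon"]
    return lms, etalon_scale(float(et["px"]), float(et["mm"]))


def load_frame_json(path: str | Path) -> AnatomicalFrame3D:
    data = json.loads(Path(path).read_text())

    def plane(key):
        return Plane(np.asarray(data[key]["point"], float),
                     np.asarray(data[key]["normal"], float))

    return AnatomicalFrame3D(
        occlusion_plane=plane("occlusion_plane"),
        mandibular_plane=plane("mandibular_plane"),
        ME=data["ME"], GO_left=data["GO_left"], GO_right=data["GO_right"],
        occlusion_ref=data.get("occlusion_ref"),
    )


def axis_to_json(axis: AxisLine, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "point": axis.point.tolist(),
        "direction": axis.direction.tolist(),
    }, indent=1) + "\n")
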