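"""Synthetic bone populations with known ground truth.

Two shape families stand in for scanned specimens so the whole pipeline is
testable without any imaging data:

``tube``
    A long-bone-like surface: L elliptical cross-sections stacked along the
    long axis with a gentle anterior bow.  Four morphometric parameters
    drive it — total length and the proximal / midshaft / distal widths,
    blended along the shaft by a fixed quadratic (Lagrange) basis.

``horseshoe``
    A mandible-like surface: a U-shaped centerline swept with an elliptical
    cross-section, arms rising at the ends.  Parameters: bigonial width,
    arch depth, ramus height and body (cross-section) height.

Every point coordinate is an *exactly affine* function of the parameters,
``coord = b0 + sum_k b_k d_k + N(0, sigma^2)``, and the generating
coefficient tensor is returned alongside the clouds, so regression fits can
be checked against truth.  Landmarks (menton/gonion analogues, plate
reference points) sit at fixed grid indices, hence are corresponded across
specimens by construction.

The default noise level of 0.3 mm reflects sub-millimetre surface error
typical of segmented CT reconstructions; parameter ranges are adult-human
plausible.  Randomness uses numpy's PCG64 generator, pinned by name in the
config so fixtures stay stable across library versions.

These stand-ins are topologically and statistically faithful, not
anatomically detailed — no cortical/trabecular structure, no condyles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .geometry3d import AxisLine, Plane
from .mandible_axis import AnatomicalFrame3D
from .plate_design import PlateSpec
from .shape_model import (
    CorrespondedCloudSet,
    MorphometricVector,
    write_clouds_wide_csv,
    write_grid_sidecar,
)

__all__ = [
    "GeneratorConfig",
    "TUBE_PARAMS",
    "HORSESHOE_PARAMS",
    "tube_coefficients",
    "horseshoe_coefficients",
    "generate_population",
    "landmark_points",
    "project_lateral",
    "make_mandible_scene",
    "make_fixture_suite",
]

TUBE_PARAMS = ("length", "prox_width", "mid_width", "dist_width")
TUBE_RANGES = {
    "length": (330.0, 420.0),
    "prox_width": (65.0, 85.0),
    "mid_width": (22.0, 32.0),
    "dist_width": (40.0, 55.0),
}

HORSESHOE_PARAMS = ("bigonial_width", "arch_depth", "ramus_height", "body_height")
HORSESHOE_RANGES = {
    "bigonial_width": (85.0, 105.0),
    "arch_depth": (70.0, 90.0),
    "ramus_height": (55.0, 70.0),
    "body_height": (24.0, 32.0),
}

_BODY_Z0 = 5.0          # fixed height of the horseshoe body centerline (mm)
_BOW_MM = 3.0           # fixed anterior bow amplitude of the tube (mm)


@dataclass
class GeneratorConfig:
    bone_family: str = "tube"
    S: int = 8
    L: int = 12
    M: int = 16
    parameter_distributions: dict[str, tuple[float, float]] | None = None
    true_coefficients: np.ndarray | None = None
    noise_sigma: float = 0.3
    seed: int = 0
    landmark_plan: dict[str, tuple[int, int]] | None = None
    rng_algorithm: str = "numpy-PCG64"

    def __post_init__(self) -> None:
        if self.bone_family not in ("tube", "horseshoe"):
            raise ConfigError(f"unknown bone_family {self.bone_family!r}")
        if self.S < 1:
            raise ConfigError("S must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.L < 2 or self.M < 3:
            raise ConfigError("need L >= 2 and M >= 3")
        if self.rng_algorithm != "numpy-PCG64":
            raise ConfigError("only the pinned numpy-PCG64 generator is supported")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return TUBE_PARAMS if self.bone_family == "tube" else HORSESHOE_PARAMS

    def ranges(self) -> dict[str, tuple[float, float]]:
        base = TUBE_RANGES if self.bone_family == "tube" else HORSESHOE_RANGES
        if self.parameter_distributions:
            out = dict(base)
            out.update(self.parameter_distributions)
            return out
        return dict(base)

    def plan(self) -> dict[str, tuple[int, int]]:
        if self.landmark_plan is not None:
            return dict(self.landmark_plan)
        if self.bone_family == "tube":
            return {
                "prox_ant": (0, 0),
                "dist_ant": (self.L - 1, 0),
                "plate_a": (2, 0),
                "plate_b": (self.L // 2, 0),
                "plate_c": (self.L - 3, 0),
            }
        L, M = self.L, self.M
        bottom = (3 * M) // 4
        return {
            "ME": ((L - 1) // 2, bottom),
            "GO_left": ((L - 1) // 4, bottom),
            "GO_right": (L - 1 - (L - 1) // 4, bottom),
        }


# ---------------------------------------------------------------------------
# ground-truth coefficient tensors


def tube_coefficients(L: int, M: int) -> np.ndarray:
    """P x 3 x 5 affine coefficients of the tube family (column 0 = intercept,
    then length, prox_width, mid_width, dist_width)."""
    s = np.repeat(np.arange(L) / (L - 1), M)            # slice fraction, per point
    theta = np.tile(2 * np.pi * np.arange(M) / M, L)
    # quadratic Lagrange blending of the three width measurements (nodes 0, .5, 1)
    w_prox = 2 * (s - 0.5) * (s - 1.0)
    w_mid = -4 * s * (s - 1.0)
    w_dist = 2 * s * (s - 0.5)
    P = L * M
    B = np.zeros((P, 3, 5))
    B[:, 0, 0] = _BOW_MM * np.sin(np.pi * s)            # fixed anterior bow
    B[:, 0, 2] = 0.5 * np.cos(theta) * w_prox
    B[:, 0, 3] = 0.5 * np.cos(theta) * w_mid
    B[:, 0, 4] = 0.5 * np.cos(theta) * w_dist
    B[:, 1, 2] = 0.4 * np.sin(theta) * w_prox           # elliptical: 0.8 * w/2
    B[:, 1, 3] = 0.4 * np.sin(theta) * w_mid
    B[:, 1, 4] = 0.4 * np.sin(theta) * w_dist
    B[:, 2, 1] = s
    return B


def horseshoe_coefficients(L: int, M: int) -> np.ndarray:
    """P x 3 x 5 affine coefficients of the horseshoe family (column 0 =
    intercept, then bigonial_width, arch_depth, ramus_height, body_height)."""
    phi = np.repeat(-np.pi / 2 + np.pi * np.arange(L) / (L - 1), M)
    theta = np.tile(2 * np.pi * np.arange(M) / M, L)
    phi0 = np.pi / 4                                     # arm onset
    ramp = np.clip((np.abs(phi) - phi0) / (np.pi / 2 - phi0), 0.0, None) ** 2
    P = L * M
    B = np.zeros((P, 3, 5))
    # centerline: x = (d1/2) sin(phi), y = -d2 cos(phi), z = z0 + d3 * ramp
    # section:    + 0.3 d4 cos(theta) * r_hat(phi) + (d4/2) sin(theta) * z_hat
    B[:, 1, 2] = -np.cos(phi)                            # y, arch_depth
    B[:, 0, 1] = 0.5 * np.sin(phi)                       # x, bigonial_width
    B[:, 2, 3] = ramp                                    # z, ramus_height
    B[:, 0, 4] = 0.3 * np.cos(theta) * np.sin(phi)       # r_hat x-component
    B[:, 1, 4] = 0.3 * np.cos(theta) * (-np.cos(phi))    # r_hat y-component
    B[:, 2, 4] = 0.5 * np.sin(theta)
    B[:, 2, 0] = _BODY_Z0
    return B


def _family_coefficients(config: GeneratorConfig) -> np.ndarray:
    if config.true_coefficients is not None:
        B = np.asarray(config.true_coefficients, dtype=float)
        k = len(config.parameter_names)
        if B.shape != (config.L * config.M, 3, 1 + k):
            raise ConfigError(
                f"true_coefficients must be {(config.L * config.M, 3, 1 + k)}, "
                f"got {B.shape}")
        return B
    builder = (tube_coefficients if config.bone_family == "tube"
               else horseshoe_coefficients)
    return builder(config.L, config.M)


# ---------------------------------------------------------------------------
# population generation


def generate_population(config: GeneratorConfig
                        ) -> tuple[CorrespondedCloudSet, np.ndarray]:
    """Draw a corresponded population and return it with the generating
    coefficient tensor (P x 3 x (1+k))."""
    rng = np.random.default_rng(config.seed)
    names = config.parameter_names
    ranges = config.ranges()
    lo = np.array([ranges[n][0] for n in names])
    hi = np.array([ranges[n][1] for n in names])
    D = rng.uniform(lo, hi, size=(config.S, len(names)))
    B = _family_coefficients(config)
    X = np.column_stack([np.ones(config.S), D])
    clouds = np.einsum("pak,sk->spa", B, X)
    if config.noise_sigma > 0:
        clouds = clouds + rng.normal(0.0, config.noise_sigma, size=clouds.shape)
    params = [MorphometricVector(dict(zip(names, row))) for row in D]
    ids = [f"spec_{i:03d}" for i in range(config.S)]
    cloudset = CorrespondedCloudSet(
        specimen_ids=ids, clouds=clouds, parameters=params,
        grid=(config.L, config.M), bone_label=config.bone_family)
    return cloudset, B


def specimen_cloud(config: GeneratorConfig,
                   params: Mapping[str, float]) -> np.ndarray:
    """Noise-free cloud of one specimen with explicit parameter values."""
    B = _family_coefficients(config)
    x = np.concatenate([[1.0],
                        [float(params[n]) for n in config.parameter_names]])
    return B @ x


def landmark_points(cloud: np.ndarray, plan: Mapping[str, tuple[int, int]],
                    M: int) -> dict[str, np.ndarray]:
    """Resolve a landmark plan (grid indices) against one flat P x 3 cloud."""
    flat = np.asarray(cloud, dtype=float).reshape(-1, 3)
    return {name: flat[l * M + m].copy() for name, (l, m) in plan.items()}


# ---------------------------------------------------------------------------
# lateral projection (X-ray forward model)


def project_lateral(landmarks3d: Mapping[str, np.ndarray], *,
                    px_per_mm: float = 2.0, etalon_mm: float = 50.0,
                    origin_px: tuple[float, float] = (400.0, 600.0),
                    noise_px: float = 0.0,
                    rng: np.random.Generator | None = None) -> dict:
    """Orthographic lateral projection of 3D landmarks to pixel coordinates.

    The sagittal plane is x = 0: the x (medio-lateral) coordinate is dropped,
    y maps to image x and z to image y (pixel convention, y down).  An etalon
    block with known physical length is emitted so the consumer can recover
    the mm-per-pixel scale.  Optional i.i.d. Gaussian pixel noise (seeded via
    ``rng``) emulates landmark-picking error.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = {}
    for name, p in landmarks3d.items():
        p = np.asarray(p, dtype=float)
        px = np.array([origin_px[0] + px_per_mm * p[1],
                       origin_px[1] - px_per_mm * p[2]])
        if noise_px > 0:
            px = px + rng.normal(0.0, noise_px, size=2)
        out[name] = px.tolist()
    return {
        "landmarks": out,
        "etalon": {"px": px_per_mm * etalon_mm, "mm": etalon_mm},
    }


def make_mandible_scene(params: Mapping[str, float] | None = None, *,
                        noise_px: float = 0.0, seed: int = 0) -> dict:
    """Full synthetic head scene for the axis round trip.

    Builds a mandible frame (occlusion and mandibular planes, ME/GO
    landmarks), places a known medio-lateral hinge axis, and forward-projects
    everything to a 2D lateral X-ray landmark set with etalon.  Returns the
    frame, the 2D scene, and the ground-truth axis.
    """
    if params is None:
        params = {n: 0.5 * (HORSESHOE_RANGES[n][0] + HORSESHOE_RANGES[n][1])
                  for n in HORSESHOE_PARAMS}
    d1 = float(params["bigonial_width"])
    d2 = float(params["arch_depth"])
    d3 = float(params["ramus_height"])
    d4 = float(params["body_height"])
    z0 = _BODY_Z0
    ME = np.array([0.0, -d2, z0 - d4 / 2 - 2.0])
    s = np.sin(np.pi / 4)
    GO_left = np.array([-(d1 / 2) * s, -d2 * s, z0 - d4 / 2])
    GO_right = np.array([+(d1 / 2) * s, -d2 * s, z0 - d4 / 2])
    n_mand = np.cross(GO_right - ME, GO_left - ME)
    n_mand = n_mand / np.linalg.norm(n_mand)
    if n_mand[2] < 0:
        n_mand = -n_mand
    mandibular_plane = Plane(ME, n_mand)

    alpha = 0.12                                 # occlusion tilt (rad)
    n_occ = np.array([0.0, np.sin(alpha), np.cos(alpha)])
    occ_base = np.array([0.0, -d2 + 5.0, z0 + d4 / 2 + 6.0])
    occlusion_plane = Plane(occ_base, n_occ)
    e2 = np.cross(n_occ, np.array([1.0, 0.0, 0.0]))  # in-plane sagittal dir
    e2 = e2 / np.linalg.norm(e2)
    occ_pts = {
        f"occ_{i}": occ_base + a * e2 + b * np.array([1.0, 0.0, 0.0])
        for i, (a, b) in enumerate([(-4.0, 0.0), (12.0, 7.0),
                                    (26.0, -7.0), (38.0, 3.0)])
    }
    anterior = ME - 0.5 * (GO_left + GO_right)
    anterior = anterior / np.linalg.norm(anterior)
    ref_name = max(occ_pts, key=lambda n: occ_pts[n] @ anterior)

    axis_true = AxisLine(point=np.array([0.0, 6.0, z0 + d3 + 8.0]),
                         direction=np.array([1.0, 0.0, 0.0]))
    frame = AnatomicalFrame3D(
        occlusion_plane=occlusion_plane, mandibular_plane=mandibular_plane,
        ME=ME, GO_left=GO_left, GO_right=GO_right,
        occlusion_ref=occ_pts[ref_name])

    landmarks3d = {"ME": ME, "GO": GO_left, "rotation_point": axis_true.point}
    landmarks3d.update(occ_pts)
    scene2d = project_lateral(landmarks3d, noise_px=noise_px,
                              rng=np.random.default_rng(seed))
    return {
        "frame": frame,
        "scene2d": scene2d,
        "axis_true": axis_true,
        "occlusion_ref_name": ref_name,
        "params": dict(params),
    }


# ---------------------------------------------------------------------------
# fixture suite


def _frame_to_json(frame: AnatomicalFrame3D) -> dict:
    return {
        "occlusion_plane": {"point": frame.occlusion_plane.point.tolist(),
                            "normal": frame.occlusion_plane.normal.tolist()},
        "mandibular_plane": {"point": frame.mandibular_plane.point.tolist(),
                             "normal": frame.mandibular_plane.normal.tolist()},
        "ME": frame.ME.tolist(),
        "GO_left": frame.GO_left.tolist(),
        "GO_right": frame.GO_right.tolist(),
        "occlusion_ref": (None if frame.occlusion_ref is None
                          else frame.occlusion_ref.tolist()),
    }


def _dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the versioned synthetic fixture set used by tests and examples.

    Contents: an S=8 tube population and an S=6 horseshoe population (CSV
    clouds + parameter tables + grid sidecars), a noise-free straight tube
    for plate design with its landmarks and a clinical-style 3 mm plate
    spec, and a lateral-X-ray landmark scene with its 3D frame and
    ground-truth axis.  Regenerates byte-identically for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    tube_cfg = GeneratorConfig(bone_family="tube", S=8, seed=seed)
    tube, _ = generate_population(tube_cfg)
    files["tube_clouds"] = out / "tube_clouds.csv"
    write_clouds_wide_csv(files["tube_clouds"], tube.specimen_ids, tube.clouds)
    files["tube_params"] = out / "tube_params.json"
    _dump(files["tube_params"],
          {sid: pv.values for sid, pv in zip(tube.specimen_ids, tube.parameters)})
    files["tube_grid"] = out / "tube_grid.json"
    write_grid_sidecar(files["tube_grid"], tube.grid)

    horse_cfg = GeneratorConfig(bone_family="horseshoe", S=6, L=9, M=12,
                                seed=seed + 1)
    horse, _ = generate_population(horse_cfg)
    files["horseshoe_clouds"] = out / "horseshoe_clouds.csv"
    write_clouds_wide_csv(files["horseshoe_clouds"], horse.specimen_ids,
                          horse.clouds)
    files["horseshoe_params"] = out / "horseshoe_params.json"
    _dump(files["horseshoe_params"],
          {sid: pv.values for sid, pv in zip(horse.specimen_ids,
                                             horse.parameters)})
    files["horseshoe_grid"] = out / "horseshoe_grid.json"
    write_grid_sidecar(files["horseshoe_grid"], horse.grid)

    # noise-free straight tube (equal widths) for plate design
    plate_cfg = GeneratorConfig(bone_family="tube", S=1, seed=seed,
                                noise_sigma=0.0)
    plate_params = {"length": 370.0, "prox_width": 30.0,
                    "mid_width": 30.0, "dist_width": 30.0}
    plate_cloud = specimen_cloud(plate_cfg, plate_params)
    files["plate_bone"] = out / "plate_bone.csv"
    write_clouds_wide_csv(files["plate_bone"], ["plate_bone"],
                          plate_cloud[None])
    files["plate_bone_grid"] = out / "plate_bone_grid.json"
    write_grid_sidecar(files["plate_bone_grid"], (plate_cfg.L, plate_cfg.M))
    lms = landmark_points(plate_cloud, plate_cfg.plan(), plate_cfg.M)
    files["plate_landmarks"] = out / "plate_landmarks.json"
    _dump(files["plate_landmarks"], {k: v.tolist() for k, v in lms.items()})
    spec = PlateSpec(reference_point_ids=["plate_a", "plate_b", "plate_c"],
                     corridor_half_width=8.0, thickness=3.0,
                     plate_label="fixture-plate", u_cluster_gap=10.0)
    files["plate_spec"] = out / "plate_spec.json"
    spec.to_json(files["plate_spec"])

    scene = make_mandible_scene(seed=seed)
    files["scene2d"] = out / "scene2d.json"
    _dump(files["scene2d"], scene["scene2d"])
    files["frame"] = out / "frame.json"
    _dump(files["frame"], _frame_to_json(scene["frame"]))
    files["axis_truth"] = out / "axis_truth.json"
    _dump(files["axis_truth"], {
        "point": scene["axis_true"].point.tolist(),
        "direction": scene["axis_true"].direction.tolist(),
    })
    _dump(out / "fixture_manifest.json", {
        "seed": seed,
        "rng_algorithm": "numpy-PCG64",
        "files": sorted(p.name for p in files.values()),
    })
    files["manifest"] = out / "fixture_manifest.json"
    return files
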