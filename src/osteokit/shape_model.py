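"""Per-point multilinear regression models of bone point clouds.

A bone is represented as a corresponded point cloud: point index ``i`` marks
the same anatomical location on every specimen.  Each coordinate of each
point is modelled as an affine function of scalar morphometric parameters
(dimensions measured on medical images)::

    coord_i,axis(d) = b0 + b1*d1 + ... + bk*dk

All 3·P scalar regressions share one design matrix ``[1, d1, ..., dk]``
(rows = specimens) and are fitted jointly by ordinary least squares with a
numerically stable solver.  Models may store additional coefficient sets
fitted on *subsets* of the parameters, so a patient for whom only some
dimensions could be measured still gets a complete (if less accurate)
predicted cloud.

Units are millimetres throughout; coordinates live in the right-handed frame
fixed by the training set — no registration is performed here.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChecksumError,
    FormatVersionError,
    MinimumParameterError,
    MissingSubsetError,
    RankDeficientError,
    ShapeMismatchError,
    UnknownParameterError,
)

MODEL_SCHEMA = "pbm-model/1"

__all__ = [
    "MorphometricVector",
    "CorrespondedCloudSet",
    "SubsetFit",
    "ParametricBoneModel",
    "PredictedCloud",
    "fit_full_model",
    "fit_intercept_model",
    "fit_subset_model",
    "predict_cloud",
    "model_save",
    "model_load",
    "residual_report",
    "read_cloud_csv",
    "read_clouds_wide_csv",
    "write_clouds_wide_csv",
    "read_parameter_table",
    "read_patient_json",
    "read_grid_sidecar",
    "write_grid_sidecar",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MorphometricVector:
    """Ordered map of parameter name -> measured value (mm).

    May be *partial*: any subset of a model's parameter names.  Values must
    be finite and strictly positive (they are physical dimensions).
    """

    values: dict[str, float]
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = {str(k): float(v) for k, v in self.values.items()}
        for name, v in self.values.items():
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"morphometric parameter {name!r} must be finite and > 0, got {v}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def subset_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.values))


@dataclass
class CorrespondedCloudSet:
    """Training tensor of S specimens x P corresponded points x 3 coordinates.

    ``grid`` optionally records that the P points are organised as L slices of
    M points each in slice-major order (``L * M == P``), the substrate for
    spline/loft surface reconstruction.
    """

    specimen_ids: list[str]
    clouds: np.ndarray
    parameters: list[MorphometricVector]
    grid: tuple[int, int] | None = None
    bone_label: str = "bone"

    def __post_init__(self) -> None:
        self.clouds = np.asarray(self.clouds, dtype=float)
        if self.clouds.ndim != 3 or self.clouds.shape[2] != 3:
            raise ShapeMismatchError(
                f"clouds must be S x P x 3, got shape {self.clouds.shape}"
            )
        S = self.clouds.shape[0]
        if len(self.specimen_ids) != S or len(self.parameters) != S:
            raise ShapeMismatchError(
                "specimen_ids, clouds and parameters disagree on specimen count"
            )
        if S < 1:
            raise ShapeMismatchError("need at least one specimen")
        names = self.parameters[0].names
        for pv in self.parameters[1:]:
            if pv.names != names:
                raise ShapeMismatchError(
                    "all training parameter vectors must share one name set"
                )
        if self.grid is not None:
            L, M = self.grid
            if L * M != self.P:
                raise ShapeMismatchError(
                    f"grid {L}x{M} inconsistent with P={self.P}"
                )

    @property
    def S(self) -> int:
        return self.clouds.shape[0]

    @property
    def P(self) -> int:
        return self.clouds.shape[1]

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.parameters[0].names

    def design_matrix(self, subset: Sequence[str]) -> np.ndarray:
        """Design matrix [1, d_subset...] with rows = specimens."""
        cols = [np.ones(self.S)]
        for name in subset:
            cols.append(np.array([pv.values[name] for pv in self.parameters]))
        return np.column_stack(cols)


@dataclass
class SubsetFit:
    """Coefficients and diagnostics of one parameter-subset regression."""

    params: tuple[str, ...]           # in model parameter order
    coefficients: np.ndarray          # P x 3 x (1 + k), column 0 = intercept
    rmse: np.ndarray                  # training RMSE per axis, shape (3,)
    S_used: int
    cond: float                       # condition number of the normal matrix

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("subset coefficients must be finite")


@dataclass
class ParametricBoneModel:
    """Per-point regression coefficient sets keyed by parameter subset.

    The full-parameter entry always exists.  An optional training set may be
    attached so missing subsets can be fitted on demand at prediction time.
    """

    bone_label: str
    parameter_names: tuple[str, ...]
    P: int
    grid: tuple[int, int] | None = None
    coefficient_store: dict[tuple[str, ...], SubsetFit] = field(default_factory=dict)
    training_set: CorrespondedCloudSet | None = field(default=None, repr=False)
    min_parameters: int = 1
    cond_ceiling: float = 1e10

    def subset_in_model_order(self, names: Iterable[str]) -> tuple[str, ...]:
        wanted = set(names)
        unknown = wanted - set(self.parameter_names)
        if unknown:
            raise UnknownParameterError(
                f"parameters {sorted(unknown)} not in model "
                f"{list(self.parameter_names)}"
            )
        return tuple(n for n in self.parameter_names if n in wanted)

    @staticmethod
    def _key(names: Iterable[str]) -> tuple[str, ...]:
        return tuple(sorted(names))

    def get_fit(self, names: Iterable[str]) -> SubsetFit | None:
        return self.coefficient_store.get(self._key(names))

    @property
    def full_fit(self) -> SubsetFit:
        fit = self.get_fit(self.parameter_names)
        if fit is None:
            raise MissingSubsetError("model has no full-parameter fit")
        return fit


@dataclass
class PredictedCloud:
    """A personalised point cloud: P x 3 coordinates in mm."""

    points: np.ndarray
    subset_used: tuple[str, ...]
    model_ref: str
    grid: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("predicted coordinates must be finite")


# ---------------------------------------------------------------------------
# fitting


def _ols_fit(train: CorrespondedCloudSet, subset: tuple[str, ...],
             cond_ceiling: float) -> SubsetFit:
    k = len(subset)
    if train.S < k + 1:
        raise RankDeficientError(
            f"need at least {k + 1} specimens to fit {k} parameters, "
            f"have {train.S}"
        )
    X = train.design_matrix(subset)
    XtX = X.T @ X
    cond = float(np.linalg.cond(XtX))
    if not np.isfinite(cond) or cond > cond_ceiling:
        raise RankDeficientError(
            f"normal matrix condition number {cond:.3g} exceeds ceiling "
            f"{cond_ceiling:.3g} for subset {subset} (collinear or too few "
            "specimens)"
        )
    # one stable solve for all 3*P responses
    Y = train.clouds.reshape(train.S, -1)            # S x (P*3)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)        # (1+k) x (P*3)
    resid = Y - X @ B
    rmse = np.sqrt(
        np.mean(resid.reshape(train.S, train.P, 3) ** 2, axis=(0, 1))
    )
    coeffs = B.reshape(1 + k, train.P, 3).transpose(1, 2, 0)
    return SubsetFit(params=subset, coefficients=coeffs, rmse=rmse,
                     S_used=train.S, cond=cond)


def fit_full_model(train: CorrespondedCloudSet, *, min_parameters: int = 1,
                   cond_ceiling: float = 1e10,
                   attach_training: bool = True) -> ParametricBoneModel:
    """Fit the full-parameter regression for every point and axis.

    With k parameters and S specimens the shared design matrix is
    S x (1 + k); each of the 3·P coordinates gets its own coefficient row.
    ``S >= k + 1`` is required, and exactly collinear predictors are
    rejected rather than silently pseudo-inverted.
    """
    subset = train.parameter_names
    model = ParametricBoneModel(
        bone_label=train.bone_label,
        parameter_names=subset,
        P=train.P,
        grid=train.grid,
        min_parameters=min_parameters,
        cond_ceiling=cond_ceiling,
        training_set=train if attach_training else None,
    )
    fit = _ols_fit(train, subset, cond_ceiling)
    model.coefficient_store[model._key(subset)] = fit
    return model


def fit_intercept_model(train: CorrespondedCloudSet) -> ParametricBoneModel:
    """Fit a parameter-free (intercept-only) model: the per-point mean cloud.

    The degenerate but useful case for a single specimen — the "model" is
    that specimen's cloud and predicts it for any patient.
    """
    model = ParametricBoneModel(
        bone_label=train.bone_label, parameter_names=(), P=train.P,
        grid=train.grid, min_parameters=0, training_set=train)
    model.coefficient_store[()] = _ols_fit(train, (), 1e10)
    return model


def fit_subset_model(model: ParametricBoneModel, train: CorrespondedCloudSet,
                     subset: Sequence[str]) -> ParametricBoneModel:
    """Add a reduced-parameter regression to the model's coefficient store.

    The subset is refitted by OLS on its own columns (plus intercept) —
    zeroing columns of the full fit would not be the least-squares solution
    on the subset.  Existing entries are untouched.
    """
    ordered = model.subset_in_model_order(subset)
    fit = _ols_fit(train, ordered, model.cond_ceiling)
    model.coefficient_store[model._key(ordered)] = fit
    return model


def predict_cloud(model: ParametricBoneModel,
                  patient: MorphometricVector) -> PredictedCloud:
    """Predict a complete personalised point cloud from a (possibly partial)
    patient parameter vector.

    The coefficient entry whose subset equals exactly the provided parameter
    names is used; if absent and a training set is attached, it is fitted on
    demand.
    """
    names = patient.names
    if len(names) < model.min_parameters:
        raise MinimumParameterError(
            f"{len(names)} parameter(s) supplied but bone "
            f"{model.bone_label!r} requires at least {model.min_parameters}"
        )
    ordered = model.subset_in_model_order(names)
    fit = model.get_fit(ordered)
    if fit is None:
        if model.training_set is None:
            raise MissingSubsetError(
                f"no coefficients stored for subset {ordered} and no "
                "training set attached — refit needed"
            )
        fit_subset_model(model, model.training_set, ordered)
        fit = model.get_fit(ordered)
        assert fit is not None
    x = np.concatenate([[1.0], [patient.values[n] for n in fit.params]])
    points = fit.coefficients @ x           # (P,3,1+k) @ (1+k,) -> (P,3)
    return PredictedCloud(points=points, subset_used=fit.params,
                          model_ref=model.bone_label, grid=model.grid)


def residual_report(model: ParametricBoneModel,
                    train: CorrespondedCloudSet) -> pd.DataFrame:
    """Training RMSE per (point, axis) row, one column per stored subset.

    Lets a designer judge how much accuracy is lost when a reduced parameter
    set has to be used.
    """
    if train.P != model.P:
        raise ShapeMismatchError("training set P does not match model")
    rows = pd.MultiIndex.from_product(
        [range(model.P), ["x", "y", "z"]], names=["point", "axis"]
    )
    out = {}
    for key in sorted(model.coefficient_store):
        fit = model.coefficient_store[key]
        X = train.design_matrix(fit.params)
        pred = np.einsum("pak,sk->spa", fit.coefficients, X)
        rmse = np.sqrt(np.mean((train.clouds - pred) ** 2, axis=0))  # P x 3
        out["+".join(fit.params) if fit.params else "intercept"] = rmse.ravel()
    return pd.DataFrame(out, index=rows)


# ---------------------------------------------------------------------------
# model store (versioned human-readable JSON text file)


def _canonical_payload(model: ParametricBoneModel) -> dict:
    subsets = []
    for key in sorted(model.coefficient_store):
        fit = model.coefficient_store[key]
        subsets.append({
            "params": list(fit.params),
            "coefficients": fit.coefficients.tolist(),
            "rmse": {a: float(r) for a, r in zip("xyz", fit.rmse)},
            "S_used": int(fit.S_used),
            "cond": float(fit.cond),
        })
    return {
        "schema": MODEL_SCHEMA,
        "bone_label": model.bone_label,
        "parameter_names": list(model.parameter_names),
        "P": int(model.P),
        "grid": list(model.grid) if model.grid else None,
        "min_parameters": int(model.min_parameters),
        "subsets": subsets,
    }


def _payload_sha256(payload: dict) -> str:
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(text.encode()).hexdigest()


def model_save(model: ParametricBoneModel, path: str | Path) -> Path:
    """Write the model as a versioned JSON text file with an integrity hash.

    Float coefficients are serialised as shortest round-trip decimal text, so
    a load after save reproduces the tensors bit for bit.
    """
    if not model.coefficient_store:
        raise ValueError("refusing to save a model with an empty coefficient store")
    payload = _canonical_payload(model)
    payload["sha256"] = _payload_sha256(payload)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def model_load(path: str | Path) -> ParametricBoneModel:
    """Load a model store file, verifying schema version and checksum."""
    payload = json.loads(Path(path).read_text())
    schema = payload.get("schema")
    if schema != MODEL_SCHEMA:
        raise FormatVersionError(
            f"unknown model schema {schema!r}; this build reads {MODEL_SCHEMA!r}"
        )
    recorded = payload.pop("sha256", None)
    if recorded is not None and recorded != _payload_sha256(payload):
        raise ChecksumError(f"model file {path} failed its integrity check")
    model = ParametricBoneModel(
        bone_label=payload["bone_label"],
        parameter_names=tuple(payload["parameter_names"]),
        P=int(payload["P"]),
        grid=tuple(payload["grid"]) if payload.get("grid") else None,
        min_parameters=int(payload.get("min_parameters", 1)),
    )
    for entry in payload["subsets"]:
        fit = SubsetFit(
            params=tuple(entry["params"]),
            coefficients=np.asarray(entry["coefficients"], dtype=float),
            rmse=np.array([entry["rmse"][a] for a in "xyz"]),
            S_used=int(entry["S_used"]),
            cond=float(entry["cond"]),
        )
        if fit.coefficients.shape != (model.P, 3, 1 + len(fit.params)):
            raise ShapeMismatchError(
                f"coefficient tensor shape {fit.coefficients.shape} wrong for "
                f"P={model.P}, k={len(fit.params)}"
            )
        model.coefficient_store[model._key(fit.params)] = fit
    if model.get_fit(model.parameter_names) is None:
        raise ChecksumError("model file lacks the full-parameter subset entry")
    return model


def model_file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# file formats (CSV clouds, parameter tables, patient vectors, grid sidecars)


def read_cloud_csv(path: str | Path) -> np.ndarray:
    """Read one specimen's cloud from a CSV with header point_id,x,y,z."""
    df = pd.read_csv(path)
    df = df.sort_values("point_id")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def read_clouds_wide_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read all specimens from a wide CSV: specimen_id,point_id,x,y,z."""
    df = pd.read_csv(path)
    ids = list(dict.fromkeys(df["specimen_id"].astype(str)))
    clouds = []
    for sid in ids:
        sub = df[df["specimen_id"].astype(str) == sid].sort_values("point_id")
        clouds.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    arr = np.array(clouds)
    if arr.ndim != 3:
        raise ShapeMismatchError("specimens have differing point counts")
    return ids, arr


def write_clouds_wide_csv(path: str | Path, specimen_ids: Sequence[str],
                          clouds: np.ndarray) -> None:
    clouds = np.asarray(clouds, dtype=float)
    frames = []
    for sid, cloud in zip(specimen_ids, clouds):
        frames.append(pd.DataFrame({
            "specimen_id": sid,
            "point_id": np.arange(cloud.shape[0]),
            "x": cloud[:, 0], "y": cloud[:, 1], "z": cloud[:, 2],
        }))
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_parameter_table(path: str | Path) -> dict[str, MorphometricVector]:
    """Read per-specimen morphometric vectors from CSV or a JSON map."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {str(k): MorphometricVector(dict(v)) for k, v in data.items()}
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "specimen_id"]
    return {
        str(row["specimen_id"]): MorphometricVector(
            {n: float(row[n]) for n in names}
        )
        for _, row in df.iterrows()
    }


def read_patient_json(path: str | Path) -> MorphometricVector:
    """Patient vector as a JSON map name -> value; missing keys = missing."""
    data = json.loads(Path(path).read_text())
    return MorphometricVector({k: float(v) for k, v in data.items()})


def read_grid_sidecar(path: str | Path) -> tuple[int, int]:
    data = json.loads(Path(path).read_text())
    if data.get("order", "slice-major") != "slice-major":
        raise FormatVersionError("only slice-major grid order is supported")
    return int(data["slices"]), int(data["per_slice"])


def write_grid_sidecar(path: str | Path, grid: tuple[int, int]) -> None:
    Path(path).write_text(json.dumps(
        {"slices": grid[0], "per_slice": grid[1], "order": "slice-major"},
        indent=1) + "\n")


def cloudset_from_files(clouds_csv: str | Path,
                        params_file: str | Path,
                        grid_sidecar: str | Path | None = None,
                        bone_label: str = "bone") -> CorrespondedCloudSet:
    """Assemble a training set from the on-disk formats."""
    ids, clouds = read_clouds_wide_csv(clouds_csv)
    table = read_parameter_table(params_file)
    missing = [i for i in ids if i not in table]
    if missing:
        raise ShapeMismatchError(f"no parameters for specimens {missing}")
    grid = read_grid_sidecar(grid_sidecar) if grid_sidecar else None
    return CorrespondedCloudSet(
        specimen_ids=ids, clouds=clouds,
        parameters=[table[i] for i in ids],
        grid=grid, bone_label=bone_label,
    )
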