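"""File formats: DeepLabCut-dialect landmark CSVs, calibration JSON,
shape-model JSON and BehaviorMatrix CSV round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MEASURE_NAMES, BehaviorMatrix
from .geometry3d import LANDMARKS, CameraModel, LandmarkObservation


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ------------------------------------------------------------------ landmarks

def write_landmarks(path, xy: np.ndarray, confidence: np.ndarray) -> None:
    """Write one camera's track as CSV with <landmark>_x/_y/_likelihood
    columns, one row per frame."""
    cols = {}
    for i, lm in enumerate(LANDMARKS):
        cols[f"{lm}_x"] = xy[:, i, 0]
        cols[f"{lm}_y"] = xy[:, i, 1]
        cols[f"{lm}_likelihood"] = confidence[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_landmarks_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Read one camera CSV; returns (frames x 5 x 2 xy, frames x 5 conf)."""
    df = pd.read_csv(path)
    missing = [
        f"{lm}_{suffix}"
        for lm in LANDMARKS
        for suffix in ("x", "y", "likelihood")
        if f"{lm}_{suffix}" not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    n = len(df)
    xy = np.empty((n, len(LANDMARKS), 2))
    conf = np.empty((n, len(LANDMARKS)))
    for i, lm in enumerate(LANDMARKS):
        xy[:, i, 0] = df[f"{lm}_x"]
        xy[:, i, 1] = df[f"{lm}_y"]
        conf[:, i] = df[f"{lm}_likelihood"]
    bad = (conf > 0) & ~np.all(np.isfinite(xy), axis=2)
    if bad.any():
        raise FormatError(f"{path}: NaN coordinates with confidence > 0")
    return xy, conf


def read_landmarks(paths: dict[str, str | Path]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read per-camera CSVs, enforcing aligned frame counts."""
    data = {cid: read_landmarks_file(p) for cid, p in paths.items()}
    counts = {cid: xy.shape[0] for cid, (xy, _) in data.items()}
    if len(set(counts.values())) > 1:
        raise FormatError(f"frame-count mismatch across cameras: {counts}")
    return data


def observations_for(
    data: dict[str, tuple[np.ndarray, np.ndarray]], frame: int, landmark_idx: int
) -> list[LandmarkObservation]:
    """All cameras' observations of one landmark at one frame."""
    lm = LANDMARKS[landmark_idx]
    return [
        LandmarkObservation(
            frame=frame, camera_id=cid, landmark=lm,
            xy=tuple(xy[frame, landmark_idx]),
            confidence=float(np.clip(conf[frame, landmark_idx], 0.0, 1.0)),
        )
        for cid, (xy, conf) in data.items()
    ]


# ---------------------------------------------------------------- calibration

def write_calibration(path, cameras: dict[str, CameraModel]) -> None:
    payload = {
        cid: cam.projection.tolist() for cid, cam in cameras.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration(path) -> dict[str, CameraModel]:
    payload = json.loads(Path(path).read_text())
    return {
        cid: CameraModel(projection=np.asarray(P), camera_id=cid)
        for cid, P in payload.items()
    }


def read_correspondences(path) -> tuple[np.ndarray, np.ndarray]:
    """Correspondence CSV with columns X,Y,Z,u,v -> (world, image) arrays."""
    df = pd.read_csv(path)
    need = ["X", "Y", "Z", "u", "v"]
    if any(c not in df.columns for c in need):
        raise FormatError(f"{path}: correspondence CSV needs columns {need}")
    return df[["X", "Y", "Z"]].to_numpy(float), df[["u", "v"]].to_numpy(float)


# ----------------------------------------------------------------- shape model

def write_shape_model(path, model) -> None:
    from .shape_model import ShapeModel  # noqa: F401  (type only)

    payload = {
        "landmarks": list(LANDMARKS),
        "mean_pose": model.mean_pose.tolist(),
        "eigenposes": model.eigenposes.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
    }
    if model.explained_variance_ratio is not None:
        payload["explained_variance_ratio"] = list(
            np.asarray(model.explained_variance_ratio, dtype=float)
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_shape_model(path):
    from .shape_model import ShapeModel

    payload = json.loads(Path(path).read_text())
    evr = payload.get("explained_variance_ratio")
    return ShapeModel(
        mean_pose=np.asarray(payload["mean_pose"]),
        eigenposes=np.asarray(payload["eigenposes"]),
        eigenvalues=np.asarray(payload["eigenvalues"]),
        explained_variance_ratio=None if evr is None else np.asarray(evr),
    )


# ------------------------------------------------------------ behavior matrix

def write_behavior_matrix(values_path, meta_path, matrix: BehaviorMatrix) -> None:
    """Long-format CSV (trial, frame, measure, value) + trial metadata CSV."""
    n_tr, n_t, n_m = matrix.values.shape
    trial, frame, measure = np.meshgrid(
        np.arange(n_tr), np.arange(n_t), np.arange(n_m), indexing="ij"
    )
    long = pd.DataFrame({
        "trial": trial.ravel(),
        "frame": frame.ravel(),
        "measure": np.asarray(matrix.measure_names)[measure.ravel()],
        "value": matrix.values.ravel(),
    })
    long.to_csv(values_path, index=False)
    meta = pd.DataFrame({
        "trial": np.arange(n_tr),
        "stimulus": matrix.stimulus,
        "onset_frame": matrix.onset_index,
        "frame_rate": matrix.frame_rate,
    })
    meta.to_csv(meta_path, index=False)


def read_behavior_matrix(values_path, meta_path) -> BehaviorMatrix:
    long = pd.read_csv(values_path)
    meta = pd.read_csv(meta_path).sort_values("trial")
    n_tr = int(long["trial"].max()) + 1
    n_t = int(long["frame"].max()) + 1
    names = tuple(MEASURE_NAMES)
    m_idx = {m: i for i, m in enumerate(names)}
    values = np.full((n_tr, n_t, len(names)), np.nan)
    values[
        long["trial"].to_numpy(),
        long["frame"].to_numpy(),
        long["measure"].map(m_idx).to_numpy(),
    ] = long["value"].to_numpy()
    return BehaviorMatrix(
        values=values,
        stimulus=meta["stimulus"].to_numpy(),
        onset_index=int(meta["onset_frame"].iloc[0]),
        frame_rate=float(meta["frame_rate"].iloc[0]),
        measure_names=names,
    )


# ------------------------------------------------------------- refined tracks

def write_refined_track(path, params_list, outlier=None) -> None:
    """CSV per frame: b1..bp, row-major R, T, outlier flag."""
    rows = []
    for i, p in enumerate(params_list):
        row = {"frame": p.t}
        for j, bj in enumerate(p.b, start=1):
            row[f"b{j}"] = bj
        for j, rj in enumerate(p.R.ravel(), start=1):
            row[f"R{j}"] = rj
        for j, tj in enumerate(p.T, start=1):
            row[f"T{j}"] = tj
        row["outlier"] = bool(outlier[i]) if outlier is not None else False
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
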