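"""Postural and movement measures derived from refined pose parameters.

Nine measures per frame, split into 3 postural (rear, body elongation,
body bending) and 6 movement measures (locomotion, freezing, rigid body
rotation, and the absolute rates of change of the 3 postural measures).
Raw measures are pooled across all trials and frames and quantile-
normalized to [0, 1] per measure, giving every measure the same uniform
marginal so that no single unit dominates distances in the response
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .shape_model import PoseParameters, ShapeModel, compose_pose

MEASURE_NAMES = (
    "rear", "elong", "bend",
    "locomotion", "freeze", "rotation",
    "d_rear", "d_elong", "d_bend",
)
N_MEASURES = len(MEASURE_NAMES)
FRAME_RATE = 15.0
#: window (s) and speed threshold (cm/s) of the freezing measure
FREEZE_WINDOW_S = 0.33
FREEZE_SPEED_CMS = 0.5

EPOCHS = {"early": (0.0, 1.0), "intermediate": (1.0, 2.0), "late": (2.0, 3.0)}


@dataclass
class BehaviorMatrix:
    """Trials x timepoints x 9 measures, plus trial metadata.

    ``values`` are in [0, 1] after quantile normalization; ``onset_index``
    gives the stimulus-onset frame within each trial's time axis.
    """

    values: np.ndarray
    stimulus: np.ndarray
    onset_index: int
    frame_rate: float = FRAME_RATE
    measure_names: tuple[str, ...] = MEASURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimulus = np.asarray(self.stimulus)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.measure_names):
            raise ValueError("values must be trials x timepoints x 9")
        if self.stimulus.shape[0] != self.values.shape[0]:
            raise ValueError("one stimulus label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class InitialPosition:
    """Allocentric head state at stimulus onset (arena-centred frame)."""

    elevation: float  # deg, [-90, 90]
    azimuth: float  # deg, (-180, 180], 0 = +X axis
    head_xyz: tuple[float, float, float]  # cm


def yaw_of(R: np.ndarray) -> float:
    """Heading angle (deg) of the body x-axis image, projected on XY."""
    return float(np.degrees(np.arctan2(R[0, 1], R[0, 0])))


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def compute_measures(
    params: list[PoseParameters],
    model: ShapeModel,
    frame_rate: float = FRAME_RATE,
    freeze_window_s: float = FREEZE_WINDOW_S,
    freeze_speed: float = FREEZE_SPEED_CMS,
    outlier: np.ndarray | None = None,
) -> np.ndarray:
    """Compute the raw 9 measures per frame for one trial.

    rear        z of the head centroid (mean of nose + ears), cm
    elong       first shape coefficient b1 (sign: + = longer body)
    bend        second shape coefficient b2 (signed left/right)
    locomotion  ||Delta T_xy|| * fps, cm/s
    freeze      fraction of a centred ~0.33 s window whose mean landmark
                speed is below 0.5 cm/s
    rotation    |Delta yaw| * fps, deg/s
    d_*         absolute first differences of the postural measures * fps

    Frames marked outlier yield NaN in every measure.
    """
    n = len(params)
    poses = np.stack([compose_pose(p, model) for p in params])
    out = np.full((n, N_MEASURES), np.nan)

    head_z = poses[:, :3, 2].mean(axis=1)  # nose + both ears
    b = np.stack([p.b for p in params])
    T = np.stack([p.T for p in params])
    yaw = np.array([yaw_of(p.R) for p in params])

    out[:, 0] = head_z
    out[:, 1] = b[:, 0]
    out[:, 2] = b[:, 1] if b.shape[1] > 1 else 0.0

    dT = np.diff(T[:, :2], axis=0)
    loco = np.linalg.norm(dT, axis=1) * frame_rate
    out[1:, 3] = loco
    out[0, 3] = out[1, 3] if n > 1 else 0.0

    dyaw = np.abs(_wrap_deg(np.diff(yaw)))
    out[1:, 5] = dyaw * frame_rate
    out[0, 5] = out[1, 5] if n > 1 else 0.0

    # mean landmark speed per frame transition
    lspeed = np.linalg.norm(np.diff(poses, axis=0), axis=2).mean(axis=1) * frame_rate
    speed = np.concatenate([[lspeed[0] if n > 1 else 0.0], lspeed])
    half = max(1, int(round(freeze_window_s * frame_rate / 2)))
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        out[t, 4] = float(np.mean(speed[lo:hi] < freeze_speed))

    for j, src in ((6, 0), (7, 1), (8, 2)):
        d = np.abs(np.diff(out[:, src])) * frame_rate
        out[1:, j] = d
        out[0, j] = out[1, j] if n > 1 else 0.0

    if outlier is not None:
        out[np.asarray(outlier, dtype=bool)] = np.nan
    return out


def quantile_normalize(raw: np.ndarray) -> np.ndarray:
    """Quantile-normalize each measure to [0, 1], pooled over trials x frames.

    Value -> (rank - 1)/(N - 1) with ties averaged: the lowest value maps
    to 0, the highest to 1, and the output empirical distribution is
    uniform.  A constant measure maps to 0.5 everywhere (with a warning).
    NaNs pass through untouched.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    flat = raw.reshape(-1, raw.shape[-1])
    res = np.empty_like(flat)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        ok = np.isfinite(col)
        n_ok = int(ok.sum())
        res[:, j] = np.nan
        if n_ok == 0:
            continue
        vals = col[ok]
        if np.ptp(vals) == 0:
            warnings.warn(f"measure {j} is constant; mapped to 0.5", stacklevel=2)
            res[ok, j] = 0.5
            continue
        ranks = rankdata(vals, method="average")
        res[ok, j] = (ranks - 1.0) / (n_ok - 1.0)
    return res.reshape(raw.shape)


def shape_descriptors(pose: np.ndarray) -> tuple[float, float, float, float]:
    """Interpretation descriptors of one complete pose.

    Returns (nose-tail distance, neck-tail distance, head-to-body angle on
    the XY plane, head-to-body angle on the YZ plane); distances in cm,
    angles in deg between the head vector (neck->nose) and the body vector
    (tail->neck) projected on the named plane.
    """
    pose = np.asarray(pose, dtype=float)
    nose, neck, tail = pose[0], pose[3], pose[4]
    nt = float(np.linalg.norm(nose - tail))
    kt = float(np.linalg.norm(neck - tail))
    head = nose - neck
    body = neck - tail

    def plane_angle(u, v, axes):
        u2, v2 = u[list(axes)], v[list(axes)]
        nu, nv = np.linalg.norm(u2), np.linalg.norm(v2)
        if nu < 1e-12 or nv < 1e-12:
            raise ValueError("zero-length projected vector; angle undefined")
        c = np.clip(np.dot(u2, v2) / (nu * nv), -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    return nt, kt, plane_angle(head, body, (0, 1)), plane_angle(head, body, (1, 2))


def initial_position(pose: np.ndarray) -> InitialPosition:
    """Allocentric head elevation/azimuth and head position of one pose.

    Elevation is the vertical angle of the neck->nose vector; azimuth its
    XY direction with the +X arena axis at 0 deg; head position is the
    nose/neck midpoint.
    """
    pose = np.asarray(pose, dtype=float)
    nose, neck = pose[0], pose[3]
    v = nose - neck
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("nose coincides with neck; orientation undefined")
    elevation = float(np.degrees(np.arcsin(np.clip(v[2] / norm, -1.0, 1.0))))
    azimuth = float(np.degrees(np.arctan2(v[1], v[0])))
    head = (nose + neck) / 2.0
    return InitialPosition(elevation=elevation, azimuth=azimuth,
                           head_xyz=tuple(head))


def epoch_slice(
    matrix: BehaviorMatrix, epoch: str | tuple[float, float]
) -> np.ndarray:
    """Slice trials x frames x 9 to a named or (start_s, end_s) window
    relative to stimulus onset.

    The window covers frames [onset + start*fps, onset + end*fps); the
    0-2 s epoch at 15 Hz yields 30 timepoints (270 dims per trial over the
    9 measures).
    """
    if isinstance(epoch, str):
        if epoch not in EPOCHS:
            raise KeyError(f"unknown epoch {epoch!r}; known: {sorted(EPOCHS)}")
        start, end = EPOCHS[epoch]
    else:
        start, end = epoch
    fps = matrix.frame_rate
    lo = matrix.onset_index + int(round(start * fps))
    hi = matrix.onset_index + int(round(end * fps))
    if lo < 0 or hi > matrix.n_timepoints or lo > hi:
        raise ValueError(
            f"epoch [{start}, {end}) s exceeds recorded range "
            f"({matrix.n_timepoints} frames, onset {matrix.onset_index})"
        )
    return matrix.values[:, lo:hi, :]


def response_matrix(
    matrix: BehaviorMatrix,
    epoch: str | tuple[float, float] = (0.0, 2.0),
    measures: list[str] | None = None,
) -> np.ndarray:
    """Flatten an epoch slice into trials x (timepoints*measures) rows."""
    sub = epoch_slice(matrix, epoch)
    if measures is not None:
        idx = [matrix.measure_names.index(m) for m in measures]
        sub = sub[:, :, idx]
    return sub.reshape(sub.shape[0], -1)
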