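"""Statistical shape model of the mouse body and pose refinement.

A pose is a 5x3 matrix of landmark coordinates (nose, left ear, right ear,
neck base, tail base; cm).  Training poses are rigidly aligned by partial
Procrustes superimposition (rotation + translation, no scaling) and a PCA
on the aligned residuals yields *eigenposes*: principal directions of body
shape change around the mean pose.  Any frame is then described as

    X(t) = (X_mean + sum_i b_i(t) P_i) R(t) + T(t)

with p shape coefficients b, a rotation R and a translation T.  The model
supports outlier detection, correction of frames with 1-2 bad landmarks
from the remaining points, and a regularized refinement that alternates
closed-form Procrustes and ridge steps to denoise whole tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry3d import LANDMARKS

N_LANDMARKS = len(LANDMARKS)
DEFAULT_P = 3
#: aligned Euclidean distance to the mean pose (cm) above which a frame is an outlier
OUTLIER_DIST_CM = 5.0
#: default per-coefficient outlier bound, in units of sqrt(eigenvalue)
B_THRESHOLD_SIGMA = 4.0
DEFAULT_ALPHA = 0.001
SMOOTH_KERNEL = (0.2, 0.6, 0.2)


class AlignmentError(ValueError):
    """Raised when rigid alignment is degenerate (e.g. coincident points)."""


@dataclass(frozen=True)
class ShapeModel:
    """Mean pose + eigenposes + eigenvalues.

    ``eigenposes`` is a (p, 5, 3) array whose flattened rows are
    orthonormal; ``eigenvalues`` are the corresponding PCA variances in
    cm^2, strictly decreasing.
    """

    mean_pose: np.ndarray
    eigenposes: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.eigenposes.shape[0]

    def __post_init__(self) -> None:
        mp = np.asarray(self.mean_pose, dtype=float)
        ep = np.asarray(self.eigenposes, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if mp.shape != (N_LANDMARKS, 3):
            raise ValueError("mean_pose must be 5x3")
        if ep.ndim != 3 or ep.shape[1:] != (N_LANDMARKS, 3):
            raise ValueError("eigenposes must be p x 5 x 3")
        if ev.shape != (ep.shape[0],):
            raise ValueError("eigenvalues must match eigenpose count")
        object.__setattr__(self, "mean_pose", mp)
        object.__setattr__(self, "eigenposes", ep)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def basis(self) -> np.ndarray:
        """Eigenposes flattened to a (p, 15) orthonormal matrix."""
        return self.eigenposes.reshape(self.p, -1)


@dataclass
class PoseParameters:
    """Per-frame decomposition: shape coefficients + rigid transform."""

    t: int
    b: np.ndarray
    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-6):
            raise ValueError("R must be orthogonal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det +1)")


@dataclass
class PoseTrack:
    """Time-ordered poses with validity/outlier bookkeeping."""

    frames: np.ndarray  # n x 5 x 3, NaN where missing
    valid: np.ndarray  # n x 5 bool
    outlier: np.ndarray  # n bool
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.outlier = np.asarray(self.outlier, dtype=bool)
        n = self.frames.shape[0]
        if self.frames.shape[1:] != (N_LANDMARKS, 3):
            raise ValueError("frames must be n x 5 x 3")
        if self.valid.shape != (n, N_LANDMARKS) or self.outlier.shape != (n,):
            raise ValueError("flags incongruent with frame count")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _kabsch(source_c: np.ndarray, reference_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ||reference_c - source_c @ R||_F.

    Inputs are centred point sets (rows = points).
    """
    H = source_c.T @ reference_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def partial_procrustes(
    source: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Rigidly align ``source`` onto ``reference`` (no scaling).

    Returns ``(R, T, aligned, residual)`` with ``aligned = source @ R + T``
    minimizing the Frobenius distance to ``reference``; ``residual`` is that
    minimized distance in cm.
    """
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if source.shape != reference.shape:
        raise ValueError("source and reference must have matching shapes")
    src_mean = source.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    src_c = source - src_mean
    ref_c = reference - ref_mean
    if np.linalg.norm(src_c) < 1e-12 or np.linalg.norm(ref_c) < 1e-12:
        raise AlignmentError("degenerate pose: all points coincident")
    R = _kabsch(src_c, ref_c)
    T = ref_mean - src_mean @ R
    aligned = source @ R + T
    residual = float(np.linalg.norm(aligned - reference))
    return R, T, aligned, residual


def train_ssm(poses: np.ndarray, p: int = DEFAULT_P) -> ShapeModel:
    """Train the statistical shape model on complete poses.

    Poses are aligned to the first pose, a provisional mean is computed,
    all poses are re-aligned to that mean (one generalized-Procrustes pass
    to remove reference bias) and PCA is run on the aligned residuals.
    The sign of each eigenpose is fixed so that a positive coefficient
    increases the nose-tail distance (component 1) or is left as returned
    by the SVD otherwise; signs are a pure labelling convention.
    """
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 3 or poses.shape[1:] != (N_LANDMARKS, 3):
        raise ValueError("poses must be m x 5 x 3")
    m = poses.shape[0]
    if m < p + 1:
        raise ValueError(f"need at least p+1={p + 1} poses, got {m}")
    if not np.all(np.isfinite(poses)):
        raise ValueError("training poses must be complete (finite)")

    aligned = np.stack([partial_procrustes(x, poses[0])[2] for x in poses])
    mean = aligned.mean(axis=0)
    aligned = np.stack([partial_procrustes(x, mean)[2] for x in aligned])
    mean = aligned.mean(axis=0)

    resid = (aligned - mean).reshape(m, -1)
    # PCA via SVD of the centred residual matrix
    _, s, Vt = np.linalg.svd(resid, full_matrices=False)
    var = s**2 / (m - 1)
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)

    eigenposes = Vt[:p].reshape(p, N_LANDMARKS, 3).copy()
    eigenvalues = var[:p].copy()

    # orient component 0 with increasing nose-tail distance
    nose, tail = 0, 4
    base = np.linalg.norm(mean[nose] - mean[tail])
    eps = 1e-3
    plus = mean + eps * eigenposes[0]
    if np.linalg.norm(plus[nose] - plus[tail]) < base:
        eigenposes[0] *= -1.0

    return ShapeModel(
        mean_pose=mean,
        eigenposes=eigenposes,
        eigenvalues=eigenvalues,
        explained_variance_ratio=evr[:p],
    )


def decompose_pose(
    pose: np.ndarray, model: ShapeModel
) -> tuple[PoseParameters, float]:
    """Decompose a complete pose into (b, R, T) under the model.

    The pose is aligned to the mean pose, the shape residual projected on
    the eigenposes gives b, and the inverse alignment gives the rigid
    transform such that ``compose_pose`` reproduces the input up to the
    returned residual (the part of the shape outside the p-dim subspace).
    """
    pose = np.asarray(pose, dtype=float)
    R0, T0, aligned, _ = partial_procrustes(pose, model.mean_pose)
    shape_resid = (aligned - model.mean_pose).ravel()
    b = model.basis @ shape_resid
    unexplained = float(np.linalg.norm(shape_resid - model.basis.T @ b))
    # invert aligned = pose @ R0 + T0  =>  pose = (aligned - T0) @ R0.T
    R = R0.T
    T = -T0 @ R0.T
    return PoseParameters(t=0, b=b, R=R, T=T), unexplained


def compose_pose(params: PoseParameters, model: ShapeModel) -> np.ndarray:
    """Generate the pose (X_mean + sum b_i P_i) R + T."""
    if params.b.shape != (model.p,):
        raise ValueError("coefficient count must equal model.p")
    shape = model.mean_pose + np.tensordot(params.b, model.eigenposes, axes=1)
    return shape @ params.R + params.T


def flag_outliers(
    track: PoseTrack,
    model: ShapeModel,
    dist_threshold: float = OUTLIER_DIST_CM,
    b_thresholds: np.ndarray | None = None,
) -> PoseTrack:
    """Mark frames whose aligned distance to the mean or shape coefficients
    exceed thresholds.

    Frames with any invalid landmark are flagged outright (they cannot be
    aligned).  Default coefficient bounds are 4*sqrt(eigenvalue).
    """
    if b_thresholds is None:
        b_thresholds = B_THRESHOLD_SIGMA * np.sqrt(model.eigenvalues)
    b_thresholds = np.asarray(b_thresholds, dtype=float)
    outlier = track.outlier.copy()
    for t in range(track.n_frames):
        if not track.valid[t].all():
            outlier[t] = True
            continue
        _, _, aligned, _ = partial_procrustes(track.frames[t], model.mean_pose)
        dist = np.linalg.norm(aligned - model.mean_pose)
        b = model.basis @ (aligned - model.mean_pose).ravel()
        if dist > dist_threshold or np.any(np.abs(b) > b_thresholds):
            outlier[t] = True
    return PoseTrack(
        frames=track.frames, valid=track.valid, outlier=outlier,
        frame_rate=track.frame_rate,
    )


def _subset_transform(
    pose: np.ndarray, model: ShapeModel, keep: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Align the mean-pose subset onto the observed subset; return (R, T, resid)."""
    R, T, _, resid = partial_procrustes(
        model.mean_pose[list(keep)], pose[list(keep)]
    )
    return R, T, resid


def best_landmark_subset(
    pose: np.ndarray, model: ShapeModel, subset_size: int = N_LANDMARKS - 2
) -> tuple[tuple[int, ...], np.ndarray, np.ndarray, float]:
    """Among all (n-2)-point subsets, pick the one whose rigid fit of the
    mean pose has the smallest alignment residual.

    Returns ``(kept_indices, R, T, residual)`` where R, T map model
    coordinates into the world (``mean_subset @ R + T ~ pose_subset``).
    """
    best = None
    for keep in combinations(range(N_LANDMARKS), subset_size):
        if not np.all(np.isfinite(pose[list(keep)])):
            continue
        R, T, resid = _subset_transform(pose, model, keep)
        if best is None or resid < best[3]:
            best = (keep, R, T, resid)
    if best is None:
        raise AlignmentError("no finite landmark subset of requested size")
    return best


def interpolate_b(
    b_series: np.ndarray, good: np.ndarray, t: int
) -> np.ndarray:
    """Re-estimate frame ``t``'s shape coefficients by piecewise cubic
    Hermite interpolation (PCHIP) of the neighbouring good frames.

    Falls back to nearest-good-frame values when fewer than two good frames
    exist on the series.
    """
    b_series = np.asarray(b_series, dtype=float)
    good = np.asarray(good, dtype=bool)
    idx = np.flatnonzero(good & (np.arange(len(good)) != t))
    if idx.size == 0:
        return np.zeros(b_series.shape[1])
    if idx.size == 1:
        return b_series[idx[0]].copy()
    out = np.empty(b_series.shape[1])
    for j in range(b_series.shape[1]):
        interp = PchipInterpolator(idx, b_series[idx, j], extrapolate=True)
        out[j] = interp(t)
    return out


def subset_correct(
    pose: np.ndarray,
    model: ShapeModel,
    b_interp: np.ndarray,
) -> np.ndarray:
    """Rebuild a pose with 1-2 bad landmarks from the trustworthy subset.

    ``b_interp`` supplies the shape coefficients (typically PCHIP-
    interpolated from neighbouring frames).  The subset is selected by its
    alignment residual against the mean-pose subset; the final rigid
    transform then aligns the shape-informed model pose (mean + interpolated
    shape) on that subset, so strongly deformed but correct poses are not
    skewed by the straight mean.  Returns the corrected 5x3 pose.
    """
    keep, _, _, _ = best_landmark_subset(pose, model)
    shape = model.mean_pose + np.tensordot(
        np.asarray(b_interp, dtype=float), model.eigenposes, axes=1
    )
    R, T, _, _ = partial_procrustes(shape[list(keep)], pose[list(keep)])
    return shape @ R + T


def correct_track(track: PoseTrack, model: ShapeModel) -> tuple[PoseTrack, np.ndarray]:
    """Correct flagged/incomplete frames that have at most 2 bad landmarks.

    A first pass decomposes every clean frame to build the coefficient
    series used for interpolation; flagged frames are rebuilt with
    ``subset_correct``.  Frames with more than 2 invalid landmarks stay
    outliers.  Returns the corrected track and the per-frame b series.
    """
    n = track.n_frames
    b_series = np.zeros((n, model.p))
    clean = np.zeros(n, dtype=bool)
    for t in range(n):
        if not track.outlier[t] and track.valid[t].all():
            params, _ = decompose_pose(track.frames[t], model)
            b_series[t] = params.b
            clean[t] = True

    frames = track.frames.copy()
    valid = track.valid.copy()
    outlier = track.outlier.copy()
    for t in range(n):
        if clean[t]:
            continue
        n_bad = int((~track.valid[t]).sum())
        if n_bad > 2:
            outlier[t] = True
            continue
        b_t = interpolate_b(b_series, clean, t)
        try:
            frames[t] = subset_correct(track.frames[t], model, b_t)
        except AlignmentError:
            outlier[t] = True
            continue
        valid[t] = True
        outlier[t] = False
        b_series[t] = b_t
    return (
        PoseTrack(frames=frames, valid=valid, outlier=outlier,
                  frame_rate=track.frame_rate),
        b_series,
    )


def _refine_cost(
    X_obs: np.ndarray, b: np.ndarray, R: np.ndarray, T: np.ndarray,
    model: ShapeModel, alpha: float,
) -> float:
    shape = model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)
    data = np.sum((X_obs - (shape @ R + T)) ** 2)
    return float(data + alpha * np.sum(b**2 / model.eigenvalues))


def refine_pose(
    X_obs: np.ndarray,
    model: ShapeModel,
    alpha: float = DEFAULT_ALPHA,
    tol: float = 1e-8,
    max_iter: int = 100,
    cost_history: list | None = None,
) -> tuple[PoseParameters, float, bool]:
    """Fit (b, R, T) to one observed pose by minimizing the regularized cost

        ||X_obs - (X_mean + sum b_i P_i) R + T||_F^2 + alpha sum b_i^2/lambda_i

    by alternating two globally-optimal closed-form steps: Procrustes for
    (R, T) at fixed b, and a ridge projection for b at fixed (R, T).  Each
    step can only lower the cost, so descent is monotone.  Returns the
    parameters, the final cost, and a convergence flag.
    """
    b = np.zeros(model.p)
    R = np.eye(3)
    T = np.zeros(3)
    ridge = 1.0 + alpha / model.eigenvalues
    cost = _refine_cost(X_obs, b, R, T, model, alpha)
    if cost_history is not None:
        cost_history.append(cost)
    converged = False
    for _ in range(max_iter):
        shape = model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)
        R0, T0, _, _ = partial_procrustes(shape, X_obs)
        R, T = R0, T0
        # back-rotate the observation into shape space and ridge-project
        Y = (X_obs - T) @ R.T
        b = (model.basis @ (Y - model.mean_pose).ravel()) / ridge
        new_cost = _refine_cost(X_obs, b, R, T, model, alpha)
        if cost_history is not None:
            cost_history.append(new_cost)
        if cost - new_cost < tol:
            cost = min(cost, new_cost)
            converged = True
            break
        cost = new_cost
    return PoseParameters(t=0, b=b, R=R, T=T), cost, converged


def refine_track(
    track: PoseTrack,
    model: ShapeModel,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[PoseParameters], np.ndarray, np.ndarray]:
    """Refine every non-outlier frame of a corrected track.

    Returns the per-frame parameters, final costs, and a per-frame
    convergence-failure flag (best-so-far parameters are still returned
    for flagged frames).  Outlier frames get NaN coefficients.
    """
    params_list: list[PoseParameters] = []
    costs = np.full(track.n_frames, np.nan)
    failed = np.zeros(track.n_frames, dtype=bool)
    for t in range(track.n_frames):
        if track.outlier[t]:
            params_list.append(
                PoseParameters(t=t, b=np.full(model.p, np.nan), R=np.eye(3),
                               T=np.zeros(3))
            )
            failed[t] = True
            continue
        params, cost, converged = refine_pose(track.frames[t], model, alpha)
        params.t = t
        params_list.append(params)
        costs[t] = cost
        failed[t] = not converged
    return params_list, costs, failed


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix to the nearest proper rotation via SVD."""
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def _smooth_series(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve along axis 0 with edge-truncated, renormalized weights."""
    n = series.shape[0]
    half = len(kernel) // 2
    out = np.empty_like(series, dtype=float)
    for t in range(n):
        lo = max(0, t - half)
        hi = min(n, t + half + 1)
        w = kernel[lo - (t - half) : len(kernel) - ((t + half + 1) - hi)]
        w = w / w.sum()
        out[t] = np.tensordot(w, series[lo:hi], axes=1)
    return out


def smooth_params(
    series: list[PoseParameters],
    kernel: tuple[float, ...] = SMOOTH_KERNEL,
) -> list[PoseParameters]:
    """Smooth b, R and T element-wise with the kernel, then renormalize
    each rotation to the nearest proper rotation by SVD.

    Edge frames use the truncated kernel renormalized to sum 1.
    """
    if len(series) < 3:
        raise ValueError("series must have at least 3 frames")
    kernel = np.asarray(kernel, dtype=float)
    b = _smooth_series(np.stack([p.b for p in series]), kernel)
    T = _smooth_series(np.stack([p.T for p in series]), kernel)
    Rs = _smooth_series(np.stack([p.R for p in series]), kernel)
    out = []
    for i, p in enumerate(series):
        out.append(
            PoseParameters(t=p.t, b=b[i], R=nearest_rotation(Rs[i]), T=T[i])
        )
    return out
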