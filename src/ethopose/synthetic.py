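"""Synthetic data with analytic ground truth.

Everything the pipeline consumes can be generated here: a mouse-like
statistical shape model, a four-camera overhead rig viewing a 30x30 cm
arena, pose tracks built from a motif library (run, rear, freeze-straight,
freeze-bent, turn) with Gaussian pixel noise and landmark dropout, labelled
trial ensembles with a known stimulus -> behavior-cluster joint
distribution (and its closed-form mutual information), and per-stimulus
Markov chains over primitive symbols (with the exact Bayes decoding
accuracy computable from the generators).  All outputs are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MEASURE_NAMES, N_MEASURES, BehaviorMatrix
from .geometry3d import LANDMARKS, CameraModel
from .shape_model import PoseParameters, ShapeModel, compose_pose

ARENA_CM = 30.0
IMAGE_W, IMAGE_H = 1280, 1040
FPS = 15.0

#: trial-ensemble scale of the study regime
N_TRIALS = 516
N_PER_STIMULUS = 172
STIMULI = ("flash", "loom", "sound")

MOTIFS = ("run", "rear", "freeze_straight", "freeze_bent", "turn")


# --------------------------------------------------------------- shape model

def _rigid_modes(mean_pose: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 infinitesimal rigid modes at the mean pose
    (3 translations + 3 rotations), flattened to rows of length 15."""
    n = mean_pose.shape[0]
    centred = mean_pose - mean_pose.mean(axis=0)
    modes = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        modes.append(t.ravel())
    for ax in range(3):
        K = np.zeros((3, 3))
        i, j = [(1, 2), (2, 0), (0, 1)][ax]
        K[i, j], K[j, i] = 1.0, -1.0
        modes.append((centred @ K).ravel())
    q, _ = np.linalg.qr(np.asarray(modes).T)
    return q.T  # 6 x 15


def _orthonormalize(vectors: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """Gram-Schmidt on flattened (p, 15) rows, optionally after projecting
    out the rows of ``against`` (e.g. rigid modes)."""
    out = []
    for v in vectors.reshape(len(vectors), -1):
        if against is not None:
            v = v - against.T @ (against @ v)
        for u in out:
            v = v - (v @ u) * u
        out.append(v / np.linalg.norm(v))
    return np.asarray(out).reshape(vectors.shape)


def make_truth_model() -> ShapeModel:
    """Mouse-like mean pose (nose-tail ~8 cm) with 3 designed eigenposes.

    Component 1: body elongation (nose and tail move apart along the body
    axis); component 2: lateral head/body bend; component 3: head raise.
    Eigenvalues follow the 43:31:17 explained-variance proportions typical
    of shape change in this species.
    """
    #           nose          ear_L           ear_R          neck        tail
    mean = np.array([
        [0.0, 4.0, 1.2],
        [-0.8, 3.0, 1.5],
        [0.8, 3.0, 1.5],
        [0.0, 2.2, 1.3],
        [0.0, -4.0, 0.8],
    ])
    elongation = np.array([
        [0.0, 1.0, 0.0],
        [0.0, 0.6, 0.0],
        [0.0, 0.6, 0.0],
        [0.0, 0.4, 0.0],
        [0.0, -1.0, 0.0],
    ])
    bend = np.array([
        [1.0, 0.0, 0.0],
        [0.7, 0.0, 0.0],
        [0.7, 0.0, 0.0],
        [0.3, 0.0, 0.0],
        [-0.5, 0.0, 0.0],
    ])
    head_raise = np.array([
        [0.0, -0.3, 1.0],
        [0.0, -0.2, 0.7],
        [0.0, -0.2, 0.7],
        [0.0, 0.0, 0.2],
        [0.0, 0.0, -0.1],
    ])
    mean = mean - mean.mean(axis=0)
    # shape change must be orthogonal to rigid motion, otherwise part of
    # each eigenpose would be absorbed by the Procrustes alignment
    rigid = _rigid_modes(mean)
    eigenposes = _orthonormalize(np.stack([elongation, bend, head_raise]), rigid)
    total = 1.0  # cm^2 of shape variance (2 SD elongation ~ 1.4 cm on an 8 cm body)
    eigenvalues = total * np.array([0.43, 0.31, 0.17]) / 0.91
    return ShapeModel(mean_pose=mean, eigenposes=eigenposes,
                      eigenvalues=eigenvalues)


# -------------------------------------------------------------------- cameras

def _look_at(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation with the optical axis toward the target."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(z @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z])


def make_cameras(
    n: int = 4, height: float = 60.0, focal_px: float = 1400.0
) -> dict[str, CameraModel]:
    """Four overhead cameras at the arena corners, looking at the centre."""
    cams = {}
    r = ARENA_CM * 0.6
    for i in range(n):
        ang = 2 * np.pi * i / n + np.pi / n
        pos = np.array([r * np.cos(ang), r * np.sin(ang), height])
        Rcw = _look_at(pos, np.zeros(3))
        K = np.array([
            [focal_px, 0.0, IMAGE_W / 2],
            [0.0, focal_px, IMAGE_H / 2],
            [0.0, 0.0, 1.0],
        ])
        t = -Rcw @ pos
        P = K @ np.hstack([Rcw, t[:, None]])
        cams[f"cam{i}"] = CameraModel(projection=P, camera_id=f"cam{i}")
    return cams


def calibration_correspondences(
    cameras: dict[str, CameraModel], seed: int = 0, n_points: int = 12
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Noise-free world<->image correspondences from a 3D calibration object
    spanning the arena volume (non-coplanar by construction)."""
    rng = np.random.default_rng(seed)
    world = np.column_stack([
        rng.uniform(-ARENA_CM / 2, ARENA_CM / 2, n_points),
        rng.uniform(-ARENA_CM / 2, ARENA_CM / 2, n_points),
        rng.uniform(0.0, 12.0, n_points),
    ])
    return {cid: (world, cam.project(world)) for cid, cam in cameras.items()}


@dataclass
class SyntheticScene:
    """A full rig: truth shape model, cameras, and rendering noise levels."""

    truth_model: ShapeModel
    cameras: dict[str, CameraModel]
    noise_px: float = 0.5
    noise_cm: float = 0.0  # isotropic 3D landmark jitter before projection
    dropout: float = 0.0
    corrupt_prob: float = 0.0  # per-frame chance of a gross mis-detection
    corrupt_cm: float = 10.0  # 3D magnitude of a planted mis-detection
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def make_scene(
    seed: int = 0, noise_px: float = 0.5, noise_cm: float = 0.0,
    dropout: float = 0.0, corrupt_prob: float = 0.0,
) -> SyntheticScene:
    return SyntheticScene(
        truth_model=make_truth_model(), cameras=make_cameras(),
        noise_px=noise_px, noise_cm=noise_cm, dropout=dropout,
        corrupt_prob=corrupt_prob, seed=seed,
    )


# --------------------------------------------------------------------- motifs

def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def motif_params(
    motif: str, n_frames: int, start_T: np.ndarray, start_yaw: float,
    rng: np.random.Generator, fps: float = FPS,
) -> list[PoseParameters]:
    """Ground-truth (b, R, T) trajectory for one motif segment.

    run: ~10 cm/s forward translation; rear: large head-raise coefficient;
    freeze_straight: static, elongated; freeze_bent: static, bent;
    turn: ~180 deg/s yaw rotation in place.
    """
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; known: {MOTIFS}")
    out = []
    T = start_T.astype(float).copy()
    yaw = start_yaw
    jitter = 0.02
    for t in range(n_frames):
        b = rng.normal(0.0, jitter, 3)
        if motif == "run":
            b[0] += 1.0
            heading = np.radians(yaw + 90.0)  # body +Y axis direction
            step = 10.0 / fps
            h = np.array([np.cos(heading), np.sin(heading)])
            new_xy = T[:2] + step * h
            # reflect off the arena walls (keep a margin for the body)
            lim = ARENA_CM / 2 - 4.0
            for ax in (0, 1):
                if abs(new_xy[ax]) > lim:
                    h[ax] = -h[ax]
                    new_xy = T[:2] + step * h
            T[:2] = np.clip(new_xy, -lim, lim)
            yaw = float(np.degrees(np.arctan2(h[1], h[0])) - 90.0)
        elif motif == "rear":
            # head raise oscillates (climb attempts), ~2.8 SD at peak
            b[2] += 1.2 * (0.6 + 0.4 * np.sin(2 * np.pi * t / fps))
            b[0] -= 0.6
        elif motif == "freeze_straight":
            b[0] += 1.5
        elif motif == "freeze_bent":
            b[0] -= 1.0
            b[1] += 1.6
        elif motif == "turn":
            yaw += 180.0 / fps
            b[1] += 0.8
        out.append(PoseParameters(t=t, b=b, R=_rot_z(yaw), T=T.copy()))
    return out


def simulate_track(
    scene: SyntheticScene,
    motif_program: list[tuple[str, float]],
    fps: float = FPS,
) -> dict:
    """Realize a motif program, project it into the cameras, corrupt it.

    Returns a dict with ground-truth parameters and poses, per-camera 2D
    observations (frames x 5 x 2) and confidences (frames x 5; dropped
    landmarks get confidence drawn below the 0.5 validity threshold).
    """
    rng = np.random.default_rng(scene.seed)
    params: list[PoseParameters] = []
    T = np.array([rng.uniform(-8, 8), rng.uniform(-8, 8), 0.0])
    yaw = float(rng.uniform(-180, 180))
    for motif, dur in motif_program:
        seg = motif_params(motif, int(round(dur * fps)), T, yaw, rng, fps)
        if seg:
            T = seg[-1].T.copy()
            yaw = float(np.degrees(np.arctan2(seg[-1].R[0, 1], seg[-1].R[0, 0])))
        params.extend(seg)
    for i, p in enumerate(params):
        p.t = i
    poses = np.stack([compose_pose(p, scene.truth_model) for p in params])

    n = len(params)
    rendered = poses + rng.normal(0.0, scene.noise_cm, poses.shape)
    # planted gross mis-detections: one landmark displaced in 3D so every
    # camera sees it wrong with high confidence -> an outlier pose
    corrupted = np.zeros((n, len(LANDMARKS)), dtype=bool)
    if scene.corrupt_prob > 0:
        hit_frames = rng.random(n) < scene.corrupt_prob
        for t in np.flatnonzero(hit_frames):
            lm = int(rng.integers(len(LANDMARKS)))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            rendered[t, lm] += scene.corrupt_cm * direction
            corrupted[t, lm] = True
    obs_2d: dict[str, np.ndarray] = {}
    conf: dict[str, np.ndarray] = {}
    for cid, cam in scene.cameras.items():
        proj = cam.project(rendered.reshape(-1, 3)).reshape(n, len(LANDMARKS), 2)
        proj = proj + rng.normal(0.0, scene.noise_px, proj.shape)
        c = rng.uniform(0.8, 1.0, (n, len(LANDMARKS)))
        dropped = rng.random((n, len(LANDMARKS))) < scene.dropout
        c[dropped] = rng.uniform(0.0, 0.45, int(dropped.sum()))
        obs_2d[cid] = proj
        conf[cid] = c
    return {
        "params": params, "poses": poses, "observations": obs_2d,
        "confidences": conf, "corrupted": corrupted, "fps": fps,
    }


# ------------------------------------------------------------ trial ensembles

@dataclass
class TrialEnsembleSpec:
    """Known stimulus -> cluster -> response structure for an ensemble.

    ``p_cluster_given_stimulus`` is (n_stimuli x n_clusters), rows summing
    to 1; ``templates`` is (n_clusters x timepoints x 9) in [0, 1].
    """

    n_trials: int = N_TRIALS
    p_stimulus: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0)
    )
    p_cluster_given_stimulus: np.ndarray | None = None
    templates: np.ndarray | None = None
    noise_sd: float = 0.05
    n_timepoints: int = 45
    onset_index: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.p_stimulus = np.asarray(self.p_stimulus, dtype=float)
        if not np.isclose(self.p_stimulus.sum(), 1.0):
            raise ValueError("p_stimulus must sum to 1")
        if self.p_cluster_given_stimulus is None:
            self.p_cluster_given_stimulus = default_mixing()
        self.p_cluster_given_stimulus = np.asarray(
            self.p_cluster_given_stimulus, dtype=float
        )
        if not np.allclose(self.p_cluster_given_stimulus.sum(axis=1), 1.0):
            raise ValueError("p(cluster|stimulus) rows must sum to 1")
        if np.any(self.p_cluster_given_stimulus < 0):
            raise ValueError("probabilities must be nonnegative")
        if self.templates is None:
            self.templates = default_templates(
                self.p_cluster_given_stimulus.shape[1], self.n_timepoints,
                self.onset_index,
            )
        self.templates = np.asarray(self.templates, dtype=float)

    @property
    def n_clusters(self) -> int:
        return self.p_cluster_given_stimulus.shape[1]


def default_mixing() -> np.ndarray:
    """A 3-stimulus x 7-cluster one-to-many mixing analog: each stimulus
    reproducibly evokes 2-3 preferred clusters."""
    p = np.array([
        # run  rear  fz_s  fz_b  turn  dart  still
        [0.45, 0.35, 0.05, 0.05, 0.05, 0.03, 0.02],  # flash
        [0.05, 0.05, 0.55, 0.10, 0.05, 0.15, 0.05],  # loom
        [0.05, 0.05, 0.10, 0.55, 0.10, 0.05, 0.10],  # sound
    ])
    return p / p.sum(axis=1, keepdims=True)


def default_templates(
    n_clusters: int, n_timepoints: int, onset: int, seed: int = 1234
) -> np.ndarray:
    """Smooth per-cluster 9-measure response templates in [0, 1].

    Templates are flat at baseline 0.5 before onset and rise/fall to
    cluster-specific levels with cluster-specific latencies afterwards, so
    clusters are separated in the (time x measure) response space.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints)
    templates = np.full((n_clusters, n_timepoints, N_MEASURES), 0.5)
    for c in range(n_clusters):
        level = rng.uniform(0.1, 0.9, N_MEASURES)
        latency = rng.uniform(1.0, 10.0, N_MEASURES)
        width = rng.uniform(2.0, 6.0, N_MEASURES)
        for m in range(N_MEASURES):
            rise = 1.0 / (1.0 + np.exp(-(t - onset - latency[m]) / width[m]))
            templates[c, :, m] = 0.5 + (level[m] - 0.5) * rise
    return np.clip(templates, 0.0, 1.0)


def analytic_mi(spec: TrialEnsembleSpec) -> float:
    """Closed-form MI (bits) between stimulus and planted cluster."""
    ps = spec.p_stimulus
    pcs = spec.p_cluster_given_stimulus
    joint = ps[:, None] * pcs
    pc = joint.sum(axis=0)
    mask = joint > 0
    return float(
        np.sum(joint[mask] * np.log2(joint[mask] /
                                     (ps[:, None] * pc[None, :])[mask]))
    )


def simulate_trials(
    spec: TrialEnsembleSpec,
) -> tuple[BehaviorMatrix, np.ndarray, float]:
    """Draw the labelled ensemble; returns (matrix, planted clusters, MI).

    Stimuli are drawn in (almost) equal counts; each trial draws its
    cluster from p(cluster|stimulus) and emits that cluster's template plus
    Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    n_stim = len(spec.p_stimulus)
    counts = np.floor(spec.p_stimulus * spec.n_trials).astype(int)
    while counts.sum() < spec.n_trials:
        counts[int(np.argmax(spec.p_stimulus * spec.n_trials - counts))] += 1
    stim_idx = rng.permutation(np.repeat(np.arange(n_stim), counts))
    clusters = np.array([
        rng.choice(spec.n_clusters, p=spec.p_cluster_given_stimulus[s])
        for s in stim_idx
    ])
    values = spec.templates[clusters] + rng.normal(
        0.0, spec.noise_sd, (spec.n_trials, spec.n_timepoints, N_MEASURES)
    )
    values = np.clip(values, 0.0, 1.0)
    stim_labels = np.array(STIMULI)[stim_idx] if n_stim == 3 else stim_idx
    matrix = BehaviorMatrix(
        values=values, stimulus=stim_labels, onset_index=spec.onset_index,
    )
    return matrix, clusters, analytic_mi(spec)


def shared_locomotion_spec(
    n_clusters: int = 6,
    n_loco_profiles: int = 3,
    n_trials: int = N_TRIALS,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> TrialEnsembleSpec:
    """Ensemble whose locomotion channel distinguishes only
    ``n_loco_profiles`` groups while the remaining 8 measures separate all
    ``n_clusters`` — so the non-locomotion measures carry stimulus
    information that locomotion alone cannot resolve.  Stimuli are mapped
    to clusters with a near-one-to-two mixing over all clusters.
    """
    rng = np.random.default_rng(seed)
    n_t, onset = 45, 15
    templates = default_templates(n_clusters, n_t, onset, seed=seed + 1)
    loco = MEASURE_NAMES.index("locomotion")
    base = default_templates(n_loco_profiles, n_t, onset, seed=seed + 2)
    for c in range(n_clusters):
        templates[c, :, loco] = base[c % n_loco_profiles, :, loco]
    # each stimulus prefers 2 clusters, with a small leak elsewhere
    p = np.full((3, n_clusters), 0.02)
    for s in range(3):
        p[s, (2 * s) % n_clusters] += 0.5
        p[s, (2 * s + 1) % n_clusters] += 0.4
    p /= p.sum(axis=1, keepdims=True)
    return TrialEnsembleSpec(
        n_trials=n_trials, p_cluster_given_stimulus=p, templates=templates,
        noise_sd=noise_sd, n_timepoints=n_t, onset_index=onset, seed=seed,
    )


# ------------------------------------------------------------- Markov chains

def simulate_markov_sequences(
    transition_matrices: dict | list,
    n: int,
    length: int,
    seed: int = 0,
    initial: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Sample ``n`` sequences per stimulus from each first-order chain.

    ``transition_matrices`` maps stimulus labels to row-stochastic
    matrices (or is a list thereof).  Returns the flat list of symbol
    arrays and the aligned stimulus labels.
    """
    if isinstance(transition_matrices, dict):
        items = list(transition_matrices.items())
    else:
        items = list(enumerate(transition_matrices))
    rng = np.random.default_rng(seed)
    seqs: list[np.ndarray] = []
    labels: list = []
    for label, P in items:
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrices must be square")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrices must be row-stochastic")
        A = P.shape[0]
        init = np.full(A, 1.0 / A) if initial is None else np.asarray(initial)
        for _ in range(n):
            s = np.empty(length, dtype=int)
            s[0] = rng.choice(A, p=init)
            for t in range(1, length):
                s[t] = rng.choice(A, p=P[s[t - 1]])
            seqs.append(s)
            labels.append(label)
    return seqs, np.asarray(labels)


def bayes_accuracy(
    transition_matrices: list[np.ndarray],
    length: int,
    n_mc: int = 20000,
    seed: int = 0,
    initial: np.ndarray | None = None,
) -> float:
    """Exact-likelihood Bayes accuracy of the generator chains, estimated
    by Monte Carlo over generated sequences (equal class priors)."""
    mats = [np.asarray(P, dtype=float) for P in transition_matrices]
    rng = np.random.default_rng(seed)
    A = mats[0].shape[0]
    init = np.full(A, 1.0 / A) if initial is None else np.asarray(initial)
    per_class = n_mc // len(mats)
    correct = 0
    total = 0
    logs = [np.log(np.maximum(P, 1e-300)) for P in mats]
    for true_c, P in enumerate(mats):
        for _ in range(per_class):
            s = np.empty(length, dtype=int)
            s[0] = rng.choice(A, p=init)
            for t in range(1, length):
                s[t] = rng.choice(A, p=P[s[t - 1]])
            lls = [
                np.log(init[s[0]]) + float(np.sum(L[s[:-1], s[1:]]))
                for L in logs
            ]
            correct += int(np.argmax(lls) == true_c)
            total += 1
    return correct / total
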