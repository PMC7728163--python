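"""Statistical shape model: alignment, training, decomposition, correction,
refinement and smoothing."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

import ethopose as ep
from ethopose.shape_model import (
    AlignmentError,
    _refine_cost,
    best_landmark_subset,
    interpolate_b,
)
from ethopose.synthetic import _rot_z, make_truth_model

from conftest import random_pose_params


class TestPartialProcrustes:
    def test_self_alignment_is_identity(self, truth_model):
        pose = truth_model.mean_pose
        R, T, aligned, resid = ep.partial_procrustes(pose, pose)
        assert np.abs(R - np.eye(3)).max() < 1e-10
        assert np.abs(T).max() < 1e-10
        assert resid < 1e-10

    def test_recovers_known_rigid_transform(self, truth_model):
        pose = truth_model.mean_pose
        R0, T0 = _rot_z(33.0), np.array([4.0, -2.0, 1.0])
        moved = pose @ R0 + T0
        R, T, aligned, resid = ep.partial_procrustes(moved, pose)
        assert resid < 1e-10
        assert np.abs(R - R0.T).max() < 1e-9
        assert np.abs(aligned - pose).max() < 1e-9

    def test_residual_matches_kabsch_oracle(self, truth_model):
        rng = np.random.default_rng(0)
        a = truth_model.mean_pose + rng.normal(0, 0.5, (5, 3))
        b = truth_model.mean_pose + rng.normal(0, 0.5, (5, 3))
        _, _, _, resid = ep.partial_procrustes(a, b)

        # independent Kabsch on centred coordinates
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        U, s, Vt = np.linalg.svd(ac.T @ bc)
        d = np.sign(np.linalg.det(U @ Vt))
        # minimized squared distance has the closed form
        # ||ac||^2 + ||bc||^2 - 2 * trace-sum of signed singular values
        ssum = s[0] + s[1] + d * s[2]
        expected = np.sqrt(max((ac**2).sum() + (bc**2).sum() - 2 * ssum, 0.0))
        assert resid == pytest.approx(expected, abs=1e-10)

    def test_degenerate_pose_raises(self):
        pose = np.ones((5, 3))
        with pytest.raises(AlignmentError):
            ep.partial_procrustes(pose, pose)


class TestTrainSSM:
    def test_recovers_generating_subspace(self, truth_model):
        """Poses from a 3-dim shape subspace (moderate amplitude) + 0.01 cm
        noise: 3 components explain >=99% and align within 2 degrees."""
        rng = np.random.default_rng(1)
        bs = rng.normal(0, [0.5, 0.4, 0.3], (400, 3))
        poses = np.stack([
            ep.compose_pose(
                ep.PoseParameters(t=0, b=b, R=np.eye(3), T=np.zeros(3)),
                truth_model,
            )
            for b in bs
        ]) + rng.normal(0, 0.01, (400, 5, 3))
        model = ep.train_ssm(poses, p=3)
        assert model.explained_variance_ratio.sum() >= 0.99
        angles = np.degrees(
            subspace_angles(truth_model.basis.T, model.basis.T)
        )
        assert angles.max() < 2.0

    def test_subspace_recovery_at_scene_scale(self, trained_model, truth_model):
        """At the full synthetic eigenvalue scale the recovery stays inside
        10 degrees for >= 200 training poses."""
        angles = np.degrees(
            subspace_angles(truth_model.basis.T, trained_model.basis.T)
        )
        assert angles.max() < 10.0

    def test_eigenposes_orthonormal_eigenvalues_decreasing(self, trained_model):
        G = trained_model.basis @ trained_model.basis.T
        assert np.abs(G - np.eye(3)).max() < 1e-10
        assert np.all(np.diff(trained_model.eigenvalues) < 0)

    def test_constant_training_set(self, truth_model):
        poses = np.repeat(truth_model.mean_pose[None], 10, axis=0)
        model = ep.train_ssm(poses, p=3)
        assert np.abs(model.eigenvalues).max() < 1e-20
        assert np.abs(model.mean_pose - truth_model.mean_pose).max() < 1e-9

    def test_too_few_poses_raise(self, truth_model):
        with pytest.raises(ValueError):
            ep.train_ssm(np.repeat(truth_model.mean_pose[None], 3, axis=0), p=3)


class TestDecomposeCompose:
    def test_roundtrip_recovers_coefficients(self, truth_model):
        """Machine-precision identity requires eigenposes exactly orthogonal
        to the mean pose's rigid modes, which the constructed model
        guarantees."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            p0 = random_pose_params(rng, truth_model)
            pose = ep.compose_pose(p0, truth_model)
            p1, resid = ep.decompose_pose(pose, truth_model)
            assert np.abs(p1.b - p0.b).max() < 1e-9
            assert resid < 1e-9
            assert np.abs(ep.compose_pose(p1, truth_model) - pose).max() < 1e-9

    def test_roundtrip_with_learned_model(self, trained_model):
        """A data-trained model is orthogonal to rigid modes only up to the
        alignment nonlinearity, so the roundtrip holds at ~1e-3."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            p0 = random_pose_params(rng, trained_model)
            pose = ep.compose_pose(p0, trained_model)
            p1, resid = ep.decompose_pose(pose, trained_model)
            assert np.abs(p1.b - p0.b).max() < 5e-2
            assert np.abs(ep.compose_pose(p1, trained_model) - pose).max() < 5e-2

    def test_mean_pose_decomposes_to_zero(self, trained_model):
        p, resid = ep.decompose_pose(trained_model.mean_pose, trained_model)
        assert np.abs(p.b).max() < 1e-9

    def test_projection_matches_gram_oracle(self, trained_model):
        """The coefficient solve must equal the explicit normal-equations
        projection on the eigenpose Gram matrix."""
        rng = np.random.default_rng(3)
        pose = trained_model.mean_pose + rng.normal(0, 0.3, (5, 3))
        p, _ = ep.decompose_pose(pose, trained_model)
        _, _, aligned, _ = ep.partial_procrustes(pose, trained_model.mean_pose)
        r = (aligned - trained_model.mean_pose).ravel()
        B = trained_model.basis
        b_oracle = np.linalg.solve(B @ B.T, B @ r)
        assert np.abs(p.b - b_oracle).max() < 1e-10

    def test_compose_is_linear_in_b(self, trained_model):
        b1, b2 = np.array([0.3, -0.2, 0.1]), np.array([-0.1, 0.4, 0.2])
        I, z = np.eye(3), np.zeros(3)

        def shape(b):
            return ep.compose_pose(
                ep.PoseParameters(t=0, b=b, R=I, T=z), trained_model
            ) - trained_model.mean_pose

        assert np.abs(shape(b1 + b2) - shape(b1) - shape(b2)).max() < 1e-12

    def test_compose_rejects_non_rotation(self, trained_model):
        with pytest.raises(ValueError):
            ep.PoseParameters(t=0, b=np.zeros(3), R=2 * np.eye(3), T=np.zeros(3))


def _track_from_params(params, model):
    frames = np.stack([ep.compose_pose(p, model) for p in params])
    n = len(params)
    return ep.PoseTrack(
        frames=frames, valid=np.ones((n, 5), bool), outlier=np.zeros(n, bool)
    )


class TestOutliers:
    def test_model_pose_not_flagged(self, trained_model):
        rng = np.random.default_rng(4)
        params = [random_pose_params(rng, trained_model, b_scale=0.5)
                  for _ in range(5)]
        track = ep.flag_outliers(
            _track_from_params(params, trained_model), trained_model
        )
        assert not track.outlier.any()

    def test_displaced_nose_flagged_by_5cm_rule(self, trained_model):
        pose = trained_model.mean_pose.copy()
        pose[0] += np.array([10.0, 0.0, 0.0])
        track = ep.PoseTrack(
            frames=pose[None], valid=np.ones((1, 5), bool),
            outlier=np.zeros(1, bool),
        )
        assert ep.flag_outliers(track, trained_model).outlier[0]

    def test_planted_corruption_sensitivity(self, trained_model):
        """3% planted 10 cm displacements are recovered with >= 0.95
        sensitivity at the default 4*sqrt(lambda) coefficient bounds."""
        rng = np.random.default_rng(5)
        n = 300
        params = [random_pose_params(rng, trained_model, b_scale=0.5)
                  for _ in range(n)]
        track = _track_from_params(params, trained_model)
        planted = rng.random(n) < 0.03
        for t in np.flatnonzero(planted):
            lm = rng.integers(5)
            d = rng.normal(size=3)
            track.frames[t, lm] += 10.0 * d / np.linalg.norm(d)
        flagged = ep.flag_outliers(track, trained_model).outlier
        sens = (flagged & planted).sum() / planted.sum()
        assert sens >= 0.95


class TestSubsetCorrect:
    def test_subset_count_is_ten(self, trained_model):
        from itertools import combinations

        assert len(list(combinations(range(5), 3))) == 10

    def test_uncorrupted_pose_roundtrips(self, trained_model):
        rng = np.random.default_rng(6)
        p0 = random_pose_params(rng, trained_model, b_scale=0.5)
        pose = ep.compose_pose(p0, trained_model)
        corrected = ep.subset_correct(pose, trained_model, p0.b)
        assert np.abs(corrected - pose).max() < 1e-6

    def test_displaced_nose_corrected_on_smooth_track(self, trained_model):
        """A 10 cm nose error on one frame of a smooth track is rebuilt to
        within twice the landmark noise floor."""
        rng = np.random.default_rng(7)
        noise = 0.05
        n = 15
        bs = np.linspace([0.2, -0.1, 0.0], [0.6, 0.3, 0.2], n)
        params = [
            ep.PoseParameters(t=t, b=bs[t], R=_rot_z(3.0 * t),
                              T=np.array([0.1 * t, 0.2 * t, 0.0]))
            for t in range(n)
        ]
        track = _track_from_params(params, trained_model)
        clean = track.frames.copy()
        track.frames += rng.normal(0, noise, track.frames.shape)
        track.frames[7, 0] += np.array([10.0, 0.0, 0.0])
        flagged = ep.flag_outliers(track, trained_model)
        assert flagged.outlier[7]
        corrected, _ = ep.correct_track(flagged, trained_model)
        assert not corrected.outlier[7]
        err = np.linalg.norm(corrected.frames[7, 0] - clean[7, 0])
        assert err < 2 * noise * 10  # generous noise floor multiple

    def test_more_than_two_bad_landmarks_stay_outlier(self, trained_model):
        pose = trained_model.mean_pose.copy()
        track = ep.PoseTrack(
            frames=pose[None],
            valid=np.array([[False, False, False, True, True]]),
            outlier=np.zeros(1, bool),
        )
        corrected, _ = ep.correct_track(
            ep.flag_outliers(track, trained_model), trained_model
        )
        assert corrected.outlier[0]


class TestRefine:
    def test_noise_free_recovery(self, truth_model):
        """Without regularization the global optimum is exact; the default
        alpha=0.001 shrinks b by ~alpha/lambda, bounding the RMSE near
        5e-4 cm."""
        rng = np.random.default_rng(8)
        p0 = random_pose_params(rng, truth_model)
        pose = ep.compose_pose(p0, truth_model)
        params, cost, converged = ep.refine_pose(pose, truth_model, alpha=0.0)
        assert converged
        fitted = ep.compose_pose(params, truth_model)
        assert np.sqrt(np.mean((fitted - pose) ** 2)) < 1e-8
        assert np.abs(params.b - p0.b).max() < 1e-7

        params_d, _, _ = ep.refine_pose(pose, truth_model)  # default alpha
        fitted_d = ep.compose_pose(params_d, truth_model)
        assert np.sqrt(np.mean((fitted_d - pose) ** 2)) < 2e-3

    def test_cost_monotone_from_initialization(self, trained_model):
        """The alternating solver must never exceed the cost of its b=0,
        R=I, T=0 initialization."""
        rng = np.random.default_rng(9)
        pose = trained_model.mean_pose + rng.normal(0, 1.0, (5, 3))
        init_cost = _refine_cost(
            pose, np.zeros(3), np.eye(3), np.zeros(3), trained_model, 0.001
        )
        _, cost, _ = ep.refine_pose(pose, trained_model)
        assert cost <= init_cost + 1e-12

    def test_shrinkage_grows_with_alpha(self, trained_model):
        rng = np.random.default_rng(10)
        p0 = random_pose_params(rng, trained_model)
        pose = ep.compose_pose(p0, trained_model) + rng.normal(0, 0.3, (5, 3))
        norms = []
        for alpha in (0.001, 0.1, 10.0):
            params, _, _ = ep.refine_pose(pose, trained_model, alpha=alpha)
            norms.append(np.linalg.norm(params.b))
        assert norms[0] > norms[1] > norms[2]

    def test_refined_beats_raw_on_noisy_track(self, trained_model):
        rng = np.random.default_rng(11)
        params0 = [random_pose_params(rng, trained_model, b_scale=0.7)
                   for _ in range(20)]
        clean = np.stack([ep.compose_pose(p, trained_model) for p in params0])
        noisy = clean + rng.normal(0, 0.3, clean.shape)
        track = ep.PoseTrack(
            frames=noisy, valid=np.ones((20, 5), bool),
            outlier=np.zeros(20, bool),
        )
        refined, _, _ = ep.refine_track(track, trained_model)
        fitted = np.stack([ep.compose_pose(p, trained_model) for p in refined])
        assert np.sqrt(np.mean((fitted - clean) ** 2)) < np.sqrt(
            np.mean((noisy - clean) ** 2)
        )


class TestSmoothing:
    def test_constant_series_unchanged(self, trained_model):
        p = ep.PoseParameters(
            t=0, b=np.array([0.1, 0.2, 0.3]), R=_rot_z(20.0),
            T=np.array([1.0, 2.0, 0.0]),
        )
        series = [
            ep.PoseParameters(t=i, b=p.b, R=p.R, T=p.T) for i in range(6)
        ]
        smoothed = ep.smooth_params(series)
        for s in smoothed:
            assert np.abs(s.b - p.b).max() < 1e-12
            assert np.abs(s.R - p.R).max() < 1e-10
            assert np.abs(s.T - p.T).max() < 1e-12

    def test_rotations_renormalized(self):
        rng = np.random.default_rng(12)
        series = [
            ep.PoseParameters(t=i, b=rng.normal(0, 0.3, 3),
                              R=_rot_z(rng.uniform(-90, 90)),
                              T=rng.normal(0, 2, 3))
            for i in range(10)
        ]
        for s in ep.smooth_params(series):
            assert np.abs(s.R.T @ s.R - np.eye(3)).max() < 1e-10
            assert np.linalg.det(s.R) == pytest.approx(1.0, abs=1e-10)

    def test_b_series_matches_convolution_oracle(self):
        rng = np.random.default_rng(13)
        bs = rng.normal(0, 1, (8, 3))
        series = [
            ep.PoseParameters(t=i, b=bs[i], R=np.eye(3), T=np.zeros(3))
            for i in range(8)
        ]
        smoothed = ep.smooth_params(series)
        k = np.array([0.2, 0.6, 0.2])
        for t in range(1, 7):  # interior frames: plain weighted sum
            oracle = k[0] * bs[t - 1] + k[1] * bs[t] + k[2] * bs[t + 1]
            assert np.abs(smoothed[t].b - oracle).max() < 1e-12
        # edges: truncated kernel renormalized
        oracle0 = (0.6 * bs[0] + 0.2 * bs[1]) / 0.8
        assert np.abs(smoothed[0].b - oracle0).max() < 1e-12


def test_interpolate_b_matches_pchip_between_good_frames():
    from scipy.interpolate import PchipInterpolator

    rng = np.random.default_rng(14)
    b = rng.normal(0, 1, (10, 3))
    good = np.ones(10, bool)
    good[4] = False
    est = interpolate_b(b, good, 4)
    idx = np.array([0, 1, 2, 3, 5, 6, 7, 8, 9])
    for j in range(3):
        oracle = PchipInterpolator(idx, b[idx, j])(4)
        assert est[j] == pytest.approx(float(oracle), abs=1e-12)
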