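"""Multi-camera geometry: DLT calibration and least-squares triangulation.

Cameras are modelled as plain 3x4 projective matrices mapping homogeneous
world coordinates (cm, arena-centred, z up) to homogeneous pixel
coordinates.  Calibration solves the Direct Linear Transform on known
world<->image correspondences; 3D landmarks are recovered per frame by
homogeneous linear least squares over every camera whose detection
confidence clears a validity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: landmark names in canonical row order used throughout the package
LANDMARKS = ("nose", "ear_L", "ear_R", "neck", "tail")

#: detections at or below this likelihood are treated as missing
CONF_THRESHOLD = 0.5


class CalibrationError(ValueError):
    """Raised when the correspondence geometry cannot determine a camera."""


@dataclass(frozen=True)
class CameraModel:
    """A calibrated pinhole camera as a 3x4 projection matrix.

    The matrix is defined up to scale; we store the unit-Frobenius-norm
    solution with the sign fixed so that the last element is non-negative
    when it is nonzero.
    """

    projection: np.ndarray
    camera_id: str = "cam"

    def __post_init__(self) -> None:
        P = np.asarray(self.projection, dtype=float)
        if P.shape != (3, 4):
            raise ValueError(f"projection must be 3x4, got {P.shape}")
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("projection matrix must have rank 3")
        P = P / np.linalg.norm(P)
        if P[2, 3] < 0:
            P = -P
        object.__setattr__(self, "projection", P)

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to pixel coordinates (..., 2)."""
        xyz = np.asarray(xyz, dtype=float)
        homog = np.concatenate([xyz, np.ones(xyz.shape[:-1] + (1,))], axis=-1)
        img = homog @ self.projection.T
        return img[..., :2] / img[..., 2:3]


@dataclass(frozen=True)
class LandmarkObservation:
    """One 2D detection of one landmark in one camera at one frame."""

    frame: int
    camera_id: str
    landmark: str
    xy: tuple[float, float]
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.confidence > 0 and not np.all(np.isfinite(self.xy)):
            raise ValueError("xy must be finite when confidence > 0")


@dataclass
class RawPoint3D:
    """Triangulated world point with bookkeeping.

    ``missing`` is a value, not an error: a landmark seen by fewer than two
    cameras simply cannot be triangulated on that frame.
    """

    xyz: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    n_views: int = 0
    residual: float = np.nan
    missing: bool = True


def _dlt_design(world: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Stack the 2-per-point homogeneous DLT equations into a 2n x 12 matrix."""
    n = world.shape[0]
    X = np.concatenate([world, np.ones((n, 1))], axis=1)  # n x 4
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -image[:, 0:1] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -image[:, 1:2] * X
    return A


def calibrate_dlt(
    correspondences: list[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
    camera_id: str = "cam",
) -> tuple[CameraModel, float]:
    """Calibrate one camera from 3D world <-> 2D image correspondences.

    Parameters
    ----------
    correspondences
        Either a list of ``(world_xyz, image_xy)`` pairs or a tuple of two
        arrays ``(n x 3, n x 2)``.  At least 6 non-coplanar points required.

    Returns
    -------
    (CameraModel, rmse)
        The least-squares DLT camera and its reprojection RMSE in pixels.

    Raises
    ------
    CalibrationError
        If fewer than 6 points are given or the geometry is degenerate
        (coplanar/collinear points leave the 12-vector under-determined).
    """
    if isinstance(correspondences, tuple) and len(correspondences) == 2:
        world, image = (np.asarray(a, dtype=float) for a in correspondences)
    else:
        world = np.asarray([c[0] for c in correspondences], dtype=float)
        image = np.asarray([c[1] for c in correspondences], dtype=float)
    if world.shape[0] < 6:
        raise CalibrationError("at least 6 correspondences are required")

    A = _dlt_design(world, image)
    _, s, Vt = np.linalg.svd(A, full_matrices=True)
    # Coplanar world points leave a 2-dimensional (or larger) null space.
    if s.size < 12 or s[10] < 1e-8 * s[0]:
        raise CalibrationError(
            "degenerate correspondence geometry (coplanar or collinear points)"
        )
    P = Vt[-1].reshape(3, 4)
    cam = CameraModel(projection=P, camera_id=camera_id)
    reproj = cam.project(world)
    rmse = float(np.sqrt(np.mean(np.sum((reproj - image) ** 2, axis=1))))
    return cam, rmse


def triangulate(
    observations: list[LandmarkObservation],
    cameras: dict[str, CameraModel],
    conf_threshold: float = CONF_THRESHOLD,
) -> RawPoint3D:
    """Triangulate one landmark at one frame from multi-camera detections.

    Detections with ``confidence > conf_threshold`` are valid; with fewer
    than two valid views the point is returned as missing.  The solution is
    the homogeneous linear least-squares point of the stacked per-view
    cross-product equations, i.e. plain least-square triangulation.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    valid = [o for o in observations if o.confidence > conf_threshold]
    if len(valid) < 2:
        return RawPoint3D()

    rows = []
    for obs in valid:
        P = cameras[obs.camera_id].projection
        x, y = obs.xy
        rows.append(x * P[2] - P[0])
        rows.append(y * P[2] - P[1])
    A = np.asarray(rows)
    _, _, Vt = np.linalg.svd(A)
    X = Vt[-1]
    if abs(X[3]) < 1e-12:  # point at infinity; treat as unreconstructable
        return RawPoint3D(n_views=len(valid))
    xyz = X[:3] / X[3]

    dists = [
        float(np.linalg.norm(cameras[o.camera_id].project(xyz) - np.asarray(o.xy)))
        for o in valid
    ]
    return RawPoint3D(
        xyz=xyz, n_views=len(valid), residual=float(np.mean(dists)), missing=False
    )


def triangulate_frames(
    obs_by_frame: dict[int, dict[str, list[LandmarkObservation]]],
    cameras: dict[str, CameraModel],
    conf_threshold: float = CONF_THRESHOLD,
) -> dict[int, dict[str, RawPoint3D]]:
    """Triangulate every landmark of every frame; convenience wrapper."""
    out: dict[int, dict[str, RawPoint3D]] = {}
    for frame, by_lm in obs_by_frame.items():
        out[frame] = {
            lm: triangulate(obs, cameras, conf_threshold) for lm, obs in by_lm.items()
        }
    return out
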