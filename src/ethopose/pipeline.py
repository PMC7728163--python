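"""End-to-end reconstruction: 2D landmarks -> raw 3D -> corrected/refined
pose parameters."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .geometry3d import LANDMARKS, CameraModel, triangulate
from .io import observations_for
from .shape_model import (
    PoseTrack,
    ShapeModel,
    correct_track,
    flag_outliers,
    refine_track,
    smooth_params,
)


def triangulate_track(
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    cameras: dict[str, CameraModel],
    conf_threshold: float = 0.5,
    frame_rate: float = 15.0,
) -> PoseTrack:
    """Least-squares triangulation of every landmark of every frame.

    ``data`` maps camera id to (frames x 5 x 2 xy, frames x 5 confidence)
    as returned by :func:`ethopose.io.read_landmarks`.
    """
    n = next(iter(data.values()))[0].shape[0]
    frames = np.full((n, len(LANDMARKS), 3), np.nan)
    valid = np.zeros((n, len(LANDMARKS)), dtype=bool)
    for t in range(n):
        for li in range(len(LANDMARKS)):
            obs = observations_for(data, t, li)
            pt = triangulate(obs, cameras, conf_threshold)
            if not pt.missing:
                frames[t, li] = pt.xyz
                valid[t, li] = True
    return PoseTrack(
        frames=frames, valid=valid, outlier=np.zeros(n, dtype=bool),
        frame_rate=frame_rate,
    )


def reconstruct(
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    cameras: dict[str, CameraModel],
    model: ShapeModel,
    config: RunConfig | None = None,
    smooth: bool = True,
):
    """Full reconstruction: triangulate, flag/correct outliers, refine,
    smooth.  Returns (raw_track, corrected_track, refined parameter list).
    """
    config = config or RunConfig()
    raw = triangulate_track(
        data, cameras, config.conf_threshold, config.frame_rate
    )
    flagged = flag_outliers(
        raw, model, dist_threshold=config.outlier_dist_cm,
        b_thresholds=config.b_threshold_sigma * np.sqrt(model.eigenvalues),
    )
    corrected, _ = correct_track(flagged, model)
    params, costs, failed = refine_track(corrected, model, alpha=config.alpha)
    if smooth and not corrected.outlier.any() and len(params) >= 3:
        params = smooth_params(params, config.smooth_kernel)
    return raw, corrected, params
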