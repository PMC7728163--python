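"""Run configuration: every threshold of the pipeline in one round-trippable
YAML-backed record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline defaults:
    landmark validity threshold 0.5, outlier distance 5 cm, refinement
    regularization alpha 0.001, smoothing kernel [0.2, 0.6, 0.2], 15 Hz."""

    conf_threshold: float = 0.5
    outlier_dist_cm: float = 5.0
    b_threshold_sigma: float = 4.0
    alpha: float = 0.001
    smooth_kernel: tuple[float, float, float] = (0.2, 0.6, 0.2)
    frame_rate: float = 15.0
    freeze_window_s: float = 0.33
    freeze_speed_cms: float = 0.5
    n_eigenposes: int = 3
    epoch_s: tuple[float, float] = (0.0, 2.0)
    k_range: tuple[int, int] = (2, 30)
    cluster_repeats: int = 50
    cluster_runs: int = 100
    decode_folds: int = 10
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("smooth_kernel", "epoch_s", "k_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
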