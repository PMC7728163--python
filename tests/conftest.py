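import numpy as np
import pytest

import ethopose as ep
from ethopose import synthetic as syn


@pytest.fixture(scope="session")
def truth_model():
    return syn.make_truth_model()


@pytest.fixture(scope="session")
def cameras():
    return syn.make_cameras()


@pytest.fixture(scope="session")
def trained_model(truth_model):
    """SSM trained on 400 clean poses drawn from the truth model."""
    rng = np.random.default_rng(42)
    bs = rng.normal(0, np.sqrt(truth_model.eigenvalues), (400, 3))
    poses = np.stack([
        ep.compose_pose(
            ep.PoseParameters(t=0, b=b, R=np.eye(3), T=np.zeros(3)), truth_model
        )
        for b in bs
    ])
    poses = poses + rng.normal(0, 0.01, poses.shape)
    return ep.train_ssm(poses, p=3)


@pytest.fixture(scope="session")
def trial_ensemble():
    """Study-scale labelled ensemble: 516 trials, 3 stimuli, 7 planted clusters."""
    spec = syn.TrialEnsembleSpec(seed=7)
    matrix, clusters, mi = syn.simulate_trials(spec)
    return spec, matrix, clusters, mi


def random_pose_params(rng, model, b_scale=1.0):
    b = rng.normal(0, b_scale * np.sqrt(model.eigenvalues))
    from ethopose.synthetic import _rot_z

    return ep.PoseParameters(
        t=0, b=b, R=_rot_z(rng.uniform(-180, 180)),
        T=np.array([rng.uniform(-10, 10), rng.uniform(-10, 10), 0.0]),
    )
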