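import warnings

import numpy as np
import pytest

from gaitgrf import (
    GaitPatternParams,
    build_scaled_model,
    cohort_mean_anthropometrics,
    construct_ground_truth_grfm,
    generate_gait_pattern,
    make_standing_trajectory,
)
from gaitgrf.dynamics import compute_segment_kinematics
from gaitgrf.grf_prediction import predict_trial


@pytest.fixture(scope="session")
def model():
    return build_scaled_model(cohort_mean_anthropometrics())


@pytest.fixture(scope="session")
def typical_trial(model):
    """Two-stride noise-free typical trial with ground truth and kinematics."""
    traj = generate_gait_pattern(GaitPatternParams(pattern="typical", n_strides=2),
                                 model)
    kin = compute_segment_kinematics(traj, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gt = construct_ground_truth_grfm(traj, model)
    return traj, kin, gt


@pytest.fixture(scope="session")
def typical_prediction(model, typical_trial):
    traj, kin, _ = typical_trial
    return predict_trial(traj, model, kin=kin)


@pytest.fixture(scope="session")
def standing_trial(model):
    traj = make_standing_trajectory(model, duration=0.5)
    kin = compute_segment_kinematics(traj, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gt = construct_ground_truth_grfm(traj, model)
    return traj, kin, gt


@pytest.fixture(scope="session")
def standing_prediction(model, standing_trial):
    traj, kin, _ = standing_trial
    return predict_trial(traj, model, kin=kin)


def interior(mask_or_len, margin=3):
    """Boolean mask keeping only interior frames (numeric-differentiation
    endpoints excluded from kinetic assertions)."""
    if isinstance(mask_or_len, np.ndarray):
        out = mask_or_len.copy()
    else:
        out = np.ones(mask_or_len, bool)
    out[:margin] = False
    out[-margin:] = False
    return out
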