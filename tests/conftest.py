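import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gstride.gait import compute_stride_metrics, segment_strides, summarize_walk
from gstride.reconstruct import detect_stance, reconstruct_trajectory
from gstride.synthetic import (
    GaitGroundTruth,
    default_cohort_spec,
    generate_cohort,
    generate_gait_imu,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free walk: SL 1.0 m, GCT 1.2 s, 20 strides."""
    truth = GaitGroundTruth(stride_length=1.0, gait_cycle_time=1.2, n_strides=20)
    rec, truth = generate_gait_imu(truth, accel_noise=0.0, gyro_noise=0.0, seed=0)
    return rec, truth


@pytest.fixture(scope="session")
def clean_chain(clean_walk):
    rec, truth = clean_walk
    mask = detect_stance(rec)
    traj = reconstruct_trajectory(rec, mask)
    windows = segment_strides(traj, mask)
    metrics = [compute_stride_metrics(w, traj) for w in windows]
    return {"rec": rec, "truth": truth, "mask": mask, "traj": traj,
            "windows": windows, "metrics": metrics}


@pytest.fixture(scope="session")
def noisy_walk():
    """Default gait and default sensor noise, 25 strides."""
    truth = GaitGroundTruth(n_strides=25)
    rec, truth = generate_gait_imu(truth, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_chain(noisy_walk):
    rec, truth = noisy_walk
    mask = detect_stance(rec)
    traj = reconstruct_trajectory(rec, mask)
    windows = segment_strides(traj, mask)
    metrics = [compute_stride_metrics(w, traj) for w in windows]
    summary = summarize_walk(metrics, traj)
    return {"rec": rec, "truth": truth, "mask": mask, "traj": traj,
            "windows": windows, "metrics": metrics, "summary": summary}


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic 86 fallers + 77 non-fallers under the default recipe."""
    return generate_cohort(default_cohort_spec(), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
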