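import numpy as np
import pytest

from gstride.config import RunConfig
from gstride.ins import detect_stance, run_zupt_ekf
from gstride.metrics import strides_from_trajectory, summarize
from gstride.simulate import (CohortSimConfig, GaitProfile, NoiseModel,
                              synth_cohort, synth_imu, synth_trajectory)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_walk():
    """One 20-stride walk at the default profile with default sensor noise."""
    truth = synth_trajectory(GaitProfile())
    rec = synth_imu(truth, NoiseModel(seed=1))
    return rec, truth


@pytest.fixture(scope="session")
def noise_free_walk():
    truth = synth_trajectory(GaitProfile(n_strides=10, stride_length_m=1.0))
    rec = synth_imu(truth, NoiseModel(accel_white_sigma=0.0, gyro_white_sigma=0.0,
                                      accel_bias=0.0, gyro_bias=0.0, seed=0))
    return rec, truth


@pytest.fixture(scope="session")
def processed_walk(default_walk):
    """Full pipeline output for the default walk."""
    rec, truth = default_walk
    cfg = RunConfig()
    mask = detect_stance(rec, cfg)
    traj = run_zupt_ekf(rec, mask, cfg)
    strides = strides_from_trajectory(traj, mask, rec.gyro, cfg)
    return {"rec": rec, "truth": truth, "mask": mask, "traj": traj,
            "strides": strides, "summary": summarize(strides)}


@pytest.fixture(scope="session")
def cohort_df():
    return synth_cohort(CohortSimConfig(seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
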