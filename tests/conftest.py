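import numpy as np
import pytest

import imugait as ig


@pytest.fixture(scope="session")
def walk_params():
    """Pre-treatment self-selected walk, 10 cycles at 128 Hz."""
    p = ig.task_defaults("walk_self", group="pre")
    p.n_cycles = 10
    return p


@pytest.fixture(scope="session")
def walk_gt(walk_params):
    return ig.make_gait_profile(walk_params, seed=1)


@pytest.fixture(scope="session")
def clean_session(walk_gt):
    """Noise-free simulated walk session."""
    return ig.simulate_imu_session(walk_gt, noise=ig.ZERO_NOISE,
                                   subject="S1", visit="pre")


@pytest.fixture(scope="session")
def noisy_session(walk_gt):
    """Default-noise simulated walk session."""
    return ig.simulate_imu_session(walk_gt, noise=ig.NoiseModel(seed=7),
                                   subject="S1", visit="pre")


@pytest.fixture(scope="session")
def clean_orientations(clean_session):
    return {p: ig.estimate_orientation(s) for p, s in clean_session.streams.items()}


@pytest.fixture(scope="session")
def clean_calibration(clean_session, clean_orientations):
    statics = ig.detect_static_interval(clean_session.streams["pelvis_L5"])
    bout = ig.segment_tasks(clean_session, ["walk_self"])[0]
    return ig.functional_calibration(
        clean_session, clean_orientations,
        walk_interval=(bout.start, bout.end), static_interval=statics[0])


@pytest.fixture(scope="session")
def static_stream():
    """2 s of a perfectly level, motionless sensor."""
    n = 256
    t = np.arange(n) / 128.0
    return ig.ImuStream(
        placement="pelvis_L5", time=t,
        accel=np.tile([0.0, 0.0, 1.0], (n, 1)),
        gyro=np.zeros((n, 3)),
        mag=np.tile(ig.MAG_REFERENCE, (n, 1)),
    )
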