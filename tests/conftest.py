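import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from actisphere.imu_io import IMURecording
from actisphere.synth import ProfileConfig, generate_recording

DAY_START = dt.datetime(2022, 1, 10, 8, 0, 0)


def make_recording(accel, fs=100.0, start_clock=DAY_START, gyro=None, meta=None):
    accel = np.asarray(accel, dtype=float)
    n = len(accel)
    if gyro is None:
        gyro = np.zeros((n, 3))
    return IMURecording(
        np.arange(n) / fs, accel, gyro,
        sample_rate_hz=fs, start_clock=start_clock, subject_meta=meta,
    )


@pytest.fixture
def still_standing():
    """600 noiseless samples of upright rest: a = [0, -1, 0] g."""
    return make_recording(np.tile([0.0, -1.0, 0.0], (600, 1)))


@pytest.fixture(scope="session")
def short_daytime_recording():
    """A seeded ~17-minute daytime recording with gait bouts and events."""
    cfg = ProfileConfig(
        days=0.012,
        seed=7,
        start_clock=DAY_START,
        gait_bout_rate_per_hour=(0.2, 12.0, 12.0, 2.5),
        high_g_event_rate=60.0,
    )
    return generate_recording(cfg)
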