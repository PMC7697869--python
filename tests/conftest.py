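import numpy as np
import pytest

from sdistep import IMUTrace, G, pd_preset, simulate_gait


@pytest.fixture
def standing_trace():
    """4 s of perfectly quiet standing at 128 Hz (level sensor)."""
    fs = 128.0
    n = int(4 * fs)
    t = np.arange(n) / fs
    accel = np.tile([0.0, 0.0, G], (n, 1))
    gyro = np.zeros((n, 3))
    return IMUTrace(side="left", fs=fs, t=t, accel=accel, gyro=gyro)


@pytest.fixture(scope="session")
def pd_trial():
    """One noise-free parkinsonian-preset trial with ground truth."""
    left, right, truth = simulate_gait(pd_preset(n_steps=20, seed=7))
    return left, right, truth


@pytest.fixture(scope="session")
def noisy_pd_trial():
    """One realistic-noise parkinsonian-preset trial with ground truth."""
    cfg = pd_preset(
        n_steps=20, seed=11, accel_noise_sigma=0.05,
        gyro_noise_sigma=0.5, gyro_bias_dps=(0.3, 0.3, 0.3),
    )
    left, right, truth = simulate_gait(cfg)
    return left, right, truth
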