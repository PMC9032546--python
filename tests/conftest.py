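import numpy as np
import pytest

from bendr import ParticipantParams, TrimmedSeries, generate_recording


def make_trimmed(values, sampling_rate=100.0, channel="gyr_x", start=0):
    """Wrap a bare array as a TrimmedSeries for unit tests."""
    values = np.asarray(values, dtype=float)
    return TrimmedSeries(
        values=values,
        start_index=start,
        end_index=start + values.size,
        channel=channel,
        sampling_rate=sampling_rate,
    )


def ar1_series(n, phi=0.9, sd=1.0, seed=0):
    """Stationary AR(1) series, the canonical noisy-but-structured fixture."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


@pytest.fixture
def noiseless_params():
    return ParticipantParams(
        mean_cycle_duration=2.0,
        cv_cycle_duration=0.0,
        mean_amplitude=60.0,
        cv_amplitude=0.0,
        noise_sd_gyro=0.0,
        noise_sd_acc=0.0,
        rng_seed=0,
    )


@pytest.fixture
def noiseless_recording(noiseless_params):
    return generate_recording(noiseless_params)


@pytest.fixture
def default_recording():
    return generate_recording(ParticipantParams(rng_seed=1))
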