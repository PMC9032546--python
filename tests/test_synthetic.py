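"""Tests of the synthetic bending-and-return recording generator."""

import numpy as np
import pytest
from scipy.stats import wilcoxon

from bendr import (
    ParticipantParams,
    RecordingLayout,
    generate_cohort,
    generate_recording,
    sampen,
    segment_test,
)
from bendr.kinematics import detect_cycles, integrate_gyro


class TestNoiselessClosedForms:
    def test_gyrx_peak_and_integrated_amplitude(self, noiseless_recording):
        # peak pitch rate of the raised cosine: A * pi / T = 60 * pi / 2
        assert noiseless_recording.gyr_x.max() == pytest.approx(60 * np.pi / 2, abs=1e-6)
        trimmed = segment_test(noiseless_recording)
        angle = integrate_gyro(trimmed["gyr_x"], detrend=False)
        cycles = detect_cycles(angle)
        assert cycles.mean_amplitude == pytest.approx(60.0, abs=0.5)

    def test_accx_zero_and_accy_one_g_upright(self, noiseless_recording):
        assert np.all(noiseless_recording.acc_x == 0.0)
        # at upright (theta = 0, before the cycles) gravity projects fully on Y
        assert noiseless_recording.acc_y[0] == pytest.approx(1.0, abs=1e-12)

    def test_integration_reproduces_pitch_angle(self, noiseless_params):
        # numerically integrated GyrX must track theta within 0.1 deg everywhere
        rec = generate_recording(noiseless_params)
        dt = 1.0 / rec.sampling_rate
        angle = np.concatenate([[0.0], np.cumsum((rec.gyr_x[1:] + rec.gyr_x[:-1]) / 2 * dt)])
        onset = rec.meta["true_start_s"]
        t = rec.time
        phase = np.clip((t - onset) / 2.0, 0.0, 50.0)  # T = 2 s, 50 cycles
        theta = 60.0 * (1 - np.cos(2 * np.pi * (phase % 1.0))) / 2
        theta[(phase <= 0) | (phase >= 50.0)] = 0.0
        assert np.max(np.abs(angle - theta)) < 0.1


def test_recording_length_and_cycle_count_with_noise():
    params = ParticipantParams(
        mean_cycle_duration=2.0, cv_cycle_duration=0.05, mean_amplitude=60.0,
        noise_sd_gyro=2.0, rng_seed=1,
    )
    layout = RecordingLayout()
    rec = generate_recording(params, layout)
    expected_n = round((rec.meta["true_end_s"] + layout.tail) * params.sampling_rate)
    assert abs(rec.n_samples - expected_n) <= 1
    trimmed = segment_test(rec)
    cycles = detect_cycles(integrate_gyro(trimmed["gyr_x"]))
    assert cycles.n_cycles == 50


def test_cohort_deterministic_for_fixed_seed():
    a = generate_cohort(3, rng_seed=42)
    b = generate_cohort(3, rng_seed=42)
    for (box_a, stool_a), (box_b, stool_b) in zip(a, b):
        assert np.array_equal(box_a.gyr_x, box_b.gyr_x)
        assert np.array_equal(stool_a.acc_z, stool_b.acc_z)
        assert box_a.meta == box_b.meta


def test_zero_between_subject_cv_gives_identical_params():
    pairs = generate_cohort(3, between_subject_cv=0.0, rng_seed=0)
    base = ParticipantParams()
    for box, stool in pairs:
        # recordings differ only through their rng draws, so the analytic
        # envelope (trim span duration) reflects the shared base parameters
        assert stool.meta["true_end_s"] - stool.meta["true_start_s"] == pytest.approx(
            base.n_cycles * base.mean_cycle_duration, rel=0.05
        )


def test_cohort_box_condition_has_larger_sdx():
    pairs = generate_cohort(6, rng_seed=3)
    sdx_box = [np.std(segment_test(b)["gyr_x"].values) for b, _ in pairs]
    sdx_stool = [np.std(segment_test(s)["gyr_x"].values) for _, s in pairs]
    assert np.mean(sdx_box) > np.mean(sdx_stool)


def test_complexity_knob_monotone_in_gyro_noise():
    """Mean SampEn of GyrX increases with the gyro noise SD (the generator's
    complexity knob), significantly between adjacent levels across seeds."""
    levels = (0.5, 2.0, 8.0)
    values = {lvl: [] for lvl in levels}
    for seed in range(20):
        for lvl in levels:
            rec = generate_recording(ParticipantParams(noise_sd_gyro=lvl, rng_seed=100 + seed))
            trimmed = segment_test(rec)
            values[lvl].append(sampen(trimmed["gyr_x"].values).sampen)
    for lo, hi in zip(levels, levels[1:]):
        assert np.mean(values[hi]) > np.mean(values[lo])
        assert wilcoxon(values[lo], values[hi]).pvalue < 0.05


def test_channel_entropy_ordering_on_default_params():
    """GyrX carries the planned movement (lowest entropy), AccX none
    (highest); AccZ inherits structure from the centripetal coupling and sits
    below the unstructured GyrY."""
    pairs = generate_cohort(5, rng_seed=9)
    means = {}
    for ch in ("gyr_x", "gyr_y", "acc_x", "acc_z"):
        means[ch] = np.mean(
            [sampen(segment_test(s)[ch].values).sampen for _, s in pairs]
        )
    assert means["acc_x"] > means["gyr_x"]
    assert means["acc_z"] < means["gyr_y"]


def test_parameter_validation_names_field():
    with pytest.raises(ValueError, match="mean_amplitude"):
        ParticipantParams(mean_amplitude=-5).validate()
    with pytest.raises(ValueError, match="noise_ar1"):
        ParticipantParams(noise_ar1=1.0).validate()
    with pytest.raises(ValueError, match="n_cycles"):
        generate_recording(ParticipantParams(n_cycles=0))
    with pytest.raises(ValueError, match="n_participants"):
        generate_cohort(1)


def test_marker_must_stand_clear_of_noise():
    params = ParticipantParams(noise_sd_gyro=20.0)
    with pytest.raises(ValueError, match="marker_amplitude"):
        generate_recording(params, RecordingLayout(marker_amplitude=60.0))
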