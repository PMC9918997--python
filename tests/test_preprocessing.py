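"""Filtering, EMG envelope, synchronization and alignment contracts."""

import numpy as np
import pytest

from shoulderload import preprocessing as pp
from shoulderload.preprocessing import (
    ConfigurationError,
    FilterSpec,
    butterworth_filter,
    compute_emg_reference,
    process_emg,
    process_imu,
    process_sjrf,
    synchronize_streams,
)
from shoulderload.synthetic import (
    EMG_FS,
    IMU_FS,
    STATIC_ACTIVATION,
    SensorRecording,
    generate_static_recording,
    generate_trial,
)


def steady_amplitude(x, frac=0.5):
    """Peak amplitude over the central portion of a series."""
    n = len(x)
    mid = x[int(n * (1 - frac) / 2): int(n * (1 + frac) / 2)]
    return (mid.max() - mid.min()) / 2


class TestButterworth:
    def test_lowpass_passes_dc_exactly(self):
        x = np.full(1000, 3.7)
        y = butterworth_filter(x, 128.0, FilterSpec("low-pass", 10.0))
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_highpass_rejects_dc(self):
        x = np.full(4000, 2.5)
        y = butterworth_filter(x, 1024.0, FilterSpec("high-pass", 20.0))
        assert np.max(np.abs(y[500:-500])) < 1e-6

    def test_zero_phase_cutoff_attenuation_is_squared_halfpower(self):
        # forward-backward 4th-order at the cutoff: (1/sqrt2)^2 = 0.5
        fs, fc = 128.0, 10.0
        t = np.arange(0, 40, 1 / fs)
        y = butterworth_filter(np.sin(2 * np.pi * fc * t), fs, FilterSpec("low-pass", fc))
        assert steady_amplitude(y) == pytest.approx(0.5, abs=0.02)

    def test_cutoff_above_nyquist_names_channel(self):
        with pytest.raises(ConfigurationError, match="gyro_x"):
            butterworth_filter(np.zeros(100), 25.0, FilterSpec("low-pass", 20.0), channel="gyro_x")

    def test_zero_phase_preserves_symmetry(self, rng):
        """No group delay: an input symmetric about its midpoint filters to
        an output symmetric about the same midpoint."""
        half = rng.standard_normal(500)
        x = np.concatenate([half, half[::-1]])
        y = butterworth_filter(x, 128.0, FilterSpec("low-pass", 10.0))
        # away from boundary transients the response carries no group delay
        interior = slice(50, -50)
        np.testing.assert_allclose(y[interior], y[::-1][interior], atol=1e-4)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            butterworth_filter(np.zeros(10), 128.0, FilterSpec("low-pass", 10.0))


class TestEmg:
    def _ref(self, value=1.0):
        return pp.EmgNormalizationReference("biceps_long_head", value, (0.0, 1.0))

    def test_zero_input_gives_zero_output(self):
        t = np.arange(0, 4, 1 / EMG_FS)
        _, env = process_emg(t, np.zeros_like(t), self._ref())
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_reference_recording_normalizes_to_one(self, traits):
        static = generate_static_recording(traits, noise_sd=0.05)
        t, raw = static.emg
        a, b = static.trial_window_s
        window = (a + 0.2 * (b - a), b - 0.1 * (b - a))
        ref = compute_emg_reference(t, raw[:, 0], window, "biceps_long_head")
        _, env = process_emg(t, raw[:, 0], ref)
        grid_mask = slice(int(window[0] * 25), int(window[1] * 25))
        t25 = t[0] + np.arange(int((t[-1] - t[0]) * 25)) / 25
        sel = (t25 >= window[0]) & (t25 <= window[1])
        assert env[sel].mean() == pytest.approx(1.0, abs=0.05)

    def test_sine_envelope_matches_rectified_mean(self):
        # full-wave rectified sine of amplitude A has mean 2A/pi
        A, f = 2.0, 50.0
        t = np.arange(0, 6, 1 / EMG_FS)
        x = A * np.sin(2 * np.pi * f * t)
        _, env = process_emg(t, x, self._ref(1.0))
        plateau = env[len(env) // 4: -len(env) // 4].mean()
        assert plateau == pytest.approx(2 * A / np.pi, rel=0.1)

    def test_output_nonnegative(self, rng):
        t = np.arange(0, 3, 1 / EMG_FS)
        x = rng.standard_normal(len(t))
        _, env = process_emg(t, x, self._ref(0.5))
        assert np.all(env >= 0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            pp.EmgNormalizationReference("biceps_long_head", 0.0, (0.0, 1.0))

    def test_window_outside_recording_rejected(self):
        t = np.arange(0, 2, 1 / EMG_FS)
        with pytest.raises(ValueError, match="outside"):
            compute_emg_reference(t, np.sin(300 * t), (5.0, 6.0), "deltoid_medial")
        with pytest.raises(ValueError, match="empty"):
            compute_emg_reference(t, np.sin(300 * t), (1.0, 0.5), "deltoid_medial")


class TestResampling:
    def test_imu_constant_passthrough(self):
        t = np.arange(0, 4, 1 / IMU_FS)
        x = np.full((len(t), 2), 5.0)
        t25, y = process_imu(t, x)
        np.testing.assert_allclose(y, 5.0, atol=1e-9)
        assert abs(len(t25) - int(4 * 25)) <= 1

    def test_imu_passband_fidelity_2hz(self):
        t = np.arange(0, 8, 1 / IMU_FS)
        _, y = process_imu(t, np.sin(2 * np.pi * 2.0 * t))
        assert steady_amplitude(y) == pytest.approx(1.0, rel=0.02)

    def test_sjrf_passband_and_stopband(self):
        t = np.arange(0, 8, 1 / 100.0)
        _, y1 = process_sjrf(t, np.sin(2 * np.pi * 1.0 * t))
        assert steady_amplitude(y1) == pytest.approx(1.0, rel=0.02)
        _, y12 = process_sjrf(t, np.sin(2 * np.pi * 12.0 * t))
        assert steady_amplitude(y12) < 0.05

    def test_sjrf_rejects_nonfinite(self):
        t = np.arange(0, 2, 1 / 100.0)
        bad = np.full((len(t), 3), np.nan)
        with pytest.raises(ValueError):
            process_sjrf(t, bad)

    def test_shared_grid_is_exact(self, tiny_aligned):
        """All aligned columns live on one 25 Hz grid with zero timestamp
        mismatch between IMU-, EMG- and force-derived columns."""
        trial = next(iter(tiny_aligned.values()))
        dt = np.diff(trial.time_s)
        np.testing.assert_allclose(dt, 1 / 25.0, atol=1e-12)
        assert trial.imu.shape[0] == trial.emg.shape[0] == trial.sjrf.shape[0]


class TestSynchronization:
    def test_injected_offsets_recovered(self, traits):
        rec = generate_trial(traits, "propulsion_slow", 0, noise_sd=0.1, duration_scale=0.4)
        estimates = synchronize_streams(rec)
        for stream, est in estimates.items():
            assert abs(est - rec.stream_offsets_s[stream]) <= 1 / IMU_FS, stream

    def test_zero_offset_case(self, traits):
        rec = generate_trial(traits, "desk_work", 0, noise_sd=0.1,
                             duration_scale=0.4, with_offsets=False)
        estimates = synchronize_streams(rec)
        for est in estimates.values():
            assert abs(est) <= 1 / IMU_FS

    def test_pure_noise_streams_warn_and_zero(self, traits, rng):
        rec = generate_trial(traits, "desk_work", 0, noise_sd=0.0,
                             duration_scale=0.3, with_offsets=False)
        # replace every stream with featureless noise: no fiducial burst
        imu = {name: (t, rng.standard_normal(d.shape)) for name, (t, d) in rec.imu.items()}
        t_emg, d_emg = rec.emg
        noisy = SensorRecording(
            participant_id=rec.participant_id, activity=rec.activity,
            subtrial_index=rec.subtrial_index, imu=imu,
            emg=(t_emg, rng.standard_normal(d_emg.shape)), sjrf=rec.sjrf,
            stream_offsets_s=rec.stream_offsets_s, trial_window_s=rec.trial_window_s,
        )
        with pytest.warns(UserWarning, match="below threshold"):
            estimates = synchronize_streams(noisy, peak_threshold=0.9)
        assert all(est == 0.0 for name, est in estimates.items() if name != "upper_arm")


class TestAlignment:
    def test_aligned_trial_shapes_and_invariants(self, tiny_aligned):
        for trial in tiny_aligned.values():
            n = len(trial.time_s)
            assert trial.imu.shape == (n, 30)
            assert trial.emg.shape == (n, 2)
            assert trial.sjrf.shape == (n, 3)
            assert np.all(trial.emg >= 0)
            assert np.all(np.isfinite(trial.imu))

    def test_realignment_onto_own_grid_is_identity(self, tiny_aligned):
        """Aligning an already-aligned trial changes nothing: interpolation
        onto its own 25 Hz grid reproduces every sample."""
        trial = next(iter(tiny_aligned.values()))
        re_imu = pp._resample(trial.time_s, trial.imu, trial.time_s)
        np.testing.assert_allclose(re_imu, trial.imu, atol=1e-9)

    def test_frame_round_trip(self, tiny_aligned):
        trial = next(iter(tiny_aligned.values()))
        df = trial.to_frame()
        back = pp.AlignedTrial.from_frame(df, *trial.key)
        np.testing.assert_array_equal(back.imu, trial.imu)
        np.testing.assert_array_equal(back.sjrf, trial.sjrf)
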