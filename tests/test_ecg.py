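"""Pan-Tompkins preprocessing, R-peak detection, and heart-rate extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from painfusion.ecg import (ECGSignal, InsufficientBeatsError, RPeakSeries,
                            UnrecoverableRecordError, compute_heart_rate,
                            compute_mean_ibi, detect_r_peaks, hr_per_second,
                            pan_tompkins_preprocess, read_ecg_csv,
                            write_hr_csv)
from painfusion.synthetic import synth_ecg


class TestPreprocess:
    def test_zero_input_propagates_zero_through_all_stages(self):
        stages = pan_tompkins_preprocess(ECGSignal(np.zeros(2048), 512))
        for stage in stages:
            assert np.allclose(stage, 0.0)
            assert len(stage) == 2048

    def test_mains_frequency_strongly_attenuated(self):
        t = np.arange(4096) / 512.0
        x = np.sin(2 * np.pi * 50.0 * t)      # 50 Hz, outside the 5-15 Hz band
        band, *_ = pan_tompkins_preprocess(ECGSignal(x, 512))
        assert np.mean(band**2) < 0.05 * np.mean(x**2)

    def test_passband_frequency_preserved(self):
        t = np.arange(4096) / 512.0
        x = np.sin(2 * np.pi * 10.0 * t)
        band, *_ = pan_tompkins_preprocess(ECGSignal(x, 512))
        assert np.mean(band**2) > 0.5 * np.mean(x**2)

    def test_squared_stage_is_square_of_derivative(self):
        x = np.random.default_rng(0).normal(size=2048)
        _, deriv, squared, _ = pan_tompkins_preprocess(ECGSignal(x, 512))
        assert np.allclose(squared, deriv**2)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            pan_tompkins_preprocess(ECGSignal(np.zeros(100), 20))


class TestDetection:
    def test_clean_60_bpm_recovers_every_truth_peak(self):
        ecg = synth_ecg(60, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        peaks = detect_r_peaks(ECGSignal(ecg.samples, 512))
        assert len(peaks.indices) == len(ecg.r_peaks_truth)
        for t in ecg.r_peaks_truth:
            assert np.abs(peaks.indices - t).min() <= 10
        # zero spurious peaks
        for p in peaks.indices:
            assert np.abs(ecg.r_peaks_truth - p).min() <= 10

    def test_flat_signal_yields_empty_series_with_warning(self):
        peaks = detect_r_peaks(ECGSignal(np.zeros(2048), 512))
        assert len(peaks.indices) == 0
        assert peaks.empty_warning

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(ECGSignal(np.zeros(256), 512))

    @pytest.mark.parametrize("seed", range(5))
    def test_sensitivity_under_noise(self, seed):
        ecg = synth_ecg(75, fs=512, duration=5.5, noise_sd=0.10, seed=seed)
        peaks = detect_r_peaks(ECGSignal(ecg.samples, 512))
        tol = int(0.05 * 512)
        hits = sum(np.abs(peaks.indices - t).min() <= tol
                   for t in ecg.r_peaks_truth)
        assert hits / len(ecg.r_peaks_truth) >= 0.95

    def test_refractory_invariant(self):
        ecg = synth_ecg(140, fs=512, duration=5.5, noise_sd=0.15, seed=3)
        peaks = detect_r_peaks(ECGSignal(ecg.samples, 512))
        assert np.all(np.diff(peaks.indices) >= int(0.2 * 512))


class TestMeanIBIAndHeartRate:
    def test_uniform_spacing(self):
        ibi = compute_mean_ibi(RPeakSeries(indices=[0, 512, 1024], fs=512))
        assert ibi.mu == 512 and ibi.n == 2

    def test_mixed_spacing(self):
        ibi = compute_mean_ibi(RPeakSeries(indices=[0, 400, 1000], fs=512))
        assert ibi.mu == 500

    def test_single_peak_raises(self):
        with pytest.raises(InsufficientBeatsError):
            compute_mean_ibi(RPeakSeries(indices=[7], fs=512))

    @given(st.lists(st.integers(0, 10**6), min_size=2, max_size=40,
                    unique=True))
    def test_mean_ibi_matches_bruteforce_oracle(self, raw):
        idx = sorted(raw)
        ibi = compute_mean_ibi(RPeakSeries(indices=idx, fs=512))
        brute = sum(idx[i + 1] - idx[i] for i in range(len(idx) - 1)) / (len(idx) - 1)
        assert ibi.mu == pytest.approx(brute)
        assert ibi.mu == pytest.approx((idx[-1] - idx[0]) / ibi.n)

    @pytest.mark.parametrize("mu,fs,expected", [
        (512.0, 512, 60.0),
        (256.0, 512, 120.0),
        (426.67, 512, 72.0),
    ])
    def test_heart_rate_formula(self, mu, fs, expected):
        from painfusion.ecg import IBISummary
        hr = compute_heart_rate(IBISummary(intervals=None, n=1, mu=mu), fs)
        assert hr == pytest.approx(expected, abs=0.01)

    def test_scale_invariance_in_fs(self):
        from painfusion.ecg import IBISummary
        hr1 = compute_heart_rate(IBISummary(None, 1, mu=400.0), 500)
        hr2 = compute_heart_rate(IBISummary(None, 1, mu=800.0), 1000)
        assert hr1 == pytest.approx(hr2)


class TestHrPerSecond:
    def test_series_length_is_floor_of_window(self):
        ecg = synth_ecg(72, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        series = hr_per_second(ECGSignal(ecg.samples, 512), 5.5)
        assert len(series.values) == 5

    def test_round_trip_constant_72(self):
        ecg = synth_ecg(72, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        series = hr_per_second(ECGSignal(ecg.samples, 512), 5.5)
        assert np.abs(series.values - 72).max() <= 2

    @pytest.mark.parametrize("bpm", [50, 60, 75, 100, 140])
    def test_round_trip_recovery_all_rates(self, bpm):
        ecg = synth_ecg(bpm, fs=512, duration=5.5, noise_sd=0.0, seed=1)
        series = hr_per_second(ECGSignal(ecg.samples, 512), 5.5)
        assert np.abs(series.values - bpm).max() <= 2

    def test_missing_middle_segment_filled_with_neighbour_mean(self):
        # craft peaks leaving second 1 without any attributable beat
        peaks = RPeakSeries(indices=[0, 80, 230, 290, 350, 420, 480], fs=100)
        ecg = ECGSignal(np.zeros(500), 100)
        series = hr_per_second(ecg, 5.0, peaks=peaks)
        assert list(series.filled_mask) == [False, True, False, False, False]
        assert series.values[1] == pytest.approx(
            0.5 * (series.values[0] + series.values[2]))

    def test_boundary_gap_takes_single_nearest_value(self):
        ecg = synth_ecg(50, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        series = hr_per_second(ECGSignal(ecg.samples, 512), 5.5)
        assert series.filled_mask[-1]
        assert series.values[-1] == pytest.approx(series.values[-2])

    def test_unrecoverable_record_raises(self):
        with pytest.raises(UnrecoverableRecordError):
            hr_per_second(ECGSignal(np.zeros(2048), 512), 4.0)

    def test_window_too_short_rejected(self):
        ecg = synth_ecg(60, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            hr_per_second(ECGSignal(ecg.samples, 512), 1.0)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        ecg = synth_ecg(60, fs=512, duration=5.5, noise_sd=0.0, seed=0)
        path = tmp_path / "ecg.csv"
        pd.DataFrame({"sample_index": np.arange(len(ecg.samples)),
                      "amplitude": ecg.samples}).to_csv(path, index=False)
        loaded = read_ecg_csv(path, fs=512)
        assert np.allclose(loaded.samples, ecg.samples)
        series = hr_per_second(loaded, 5.5)
        out = tmp_path / "hr.csv"
        write_hr_csv(series, out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["second_index", "bpm", "filled_flag"]
        assert len(df) == 5
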