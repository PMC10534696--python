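"""ECG filtering, R-peak detection, beat correction and signal quality."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from egosync import synth
from egosync.ecg import (
    FLAG_MEDIAN_REJECT,
    FLAG_OK,
    HeartRateSeries,
    PeakTrain,
    compute_sqi,
    detect_rpeaks,
    detect_shifted_beats,
    filter_ecg,
    hr_from_peaks,
    median_beat_correction,
    refine_peaks_local,
    run_hr_pipeline,
)
from egosync.timebase import TimedSamples, UniformSignal, resample_nearest

RATE = 250.0


def _sine(freq, duration=20.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return UniformSignal(np.sin(2 * np.pi * freq * t), rate=rate)


def _amplitude_ratio(filtered, original):
    # steady-state amplitude, edges trimmed to avoid filter transients
    n = len(filtered.values)
    sl = slice(n // 4, 3 * n // 4)
    return np.abs(filtered.values[sl]).max() / np.abs(original.values[sl]).max()


class TestFilterEcg:
    def test_1hz_attenuated_below_one_percent(self):
        sig = _sine(1.0)
        assert _amplitude_ratio(filter_ecg(sig), sig) < 0.01

    def test_mains_attenuated_at_least_20db(self):
        for mains in (50, 60):
            sig = _sine(float(mains))
            assert _amplitude_ratio(filter_ecg(sig, mains_hz=mains), sig) < 0.1

    def test_qrs_band_mostly_preserved(self):
        sig = _sine(30.0)
        assert _amplitude_ratio(filter_ecg(sig), sig) > 0.7

    def test_zero_signal_stays_zero(self):
        sig = UniformSignal(np.zeros(5000), rate=RATE)
        assert np.allclose(filter_ecg(sig).values, 0.0)

    def test_rate_too_low_for_notch_rejected(self):
        with pytest.raises(ValueError):
            filter_ecg(UniformSignal(np.zeros(500), rate=90.0), mains_hz=50)

    def test_bad_mains_rejected(self):
        with pytest.raises(ValueError):
            filter_ecg(_sine(1.0), mains_hz=55)


def _detect_on(spec):
    e = synth.synth_ecg(spec)
    u = resample_nearest(e.ecg, RATE)
    det = detect_rpeaks(filter_ecg(u), raw=u)
    return det, e


def _match(det_times, truth, tol=0.05):
    if len(det_times) == 0:
        return 0, np.empty(0)
    d = np.abs(det_times[:, None] - truth[None, :]).min(axis=1)
    return int((d < tol).sum()), d


class TestDetectRpeaks:
    def test_clean_150bpm_counts(self):
        spec = synth.SynthSpec(seed=1, duration=60.0, hr_profile=("constant", 150.0))
        det, e = _detect_on(spec)
        assert abs(len(det) - 150) <= 1

    def test_clean_70bpm_timing_within_8ms(self):
        spec = synth.SynthSpec(seed=2, duration=60.0, hr_profile=("constant", 70.0))
        det, e = _detect_on(spec)
        tp, d = _match(det.t_peaks, e.rendered_peaks)
        assert tp == len(det)
        assert (d < 0.008).all()

    @pytest.mark.parametrize("hr", [70.0, 150.0])
    def test_noisy_sensitivity_and_ppv(self, hr):
        spec = synth.SynthSpec(seed=3, duration=120.0,
                               hr_profile=("constant", hr), noise_snr_db=15.0)
        det, e = _detect_on(spec)
        tp, d = _match(det.t_peaks, e.rendered_peaks)
        assert tp / len(e.rendered_peaks) >= 0.99
        assert tp / len(det) >= 0.99
        assert (d[d < 0.05] < 0.008).all()

    def test_flat_signal_no_peaks(self):
        det = detect_rpeaks(UniformSignal(np.zeros(10000), rate=RATE))
        assert len(det) == 0

    def test_short_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than 2 s"):
            det = detect_rpeaks(UniformSignal(np.zeros(100), rate=RATE))
        assert len(det) == 0


class TestRefinePeaksLocal:
    def _pulse_signal(self, peak_idx, n=2000):
        # smooth triangular hill centered on peak_idx
        x = np.zeros(n)
        for w in range(-10, 11):
            x[peak_idx + w] = 10.0 - abs(w)
        return UniformSignal(x, rate=RATE)

    def test_peak_at_maximum_is_fixed_point(self):
        sig = self._pulse_signal(1000)
        out = refine_peaks_local(sig, PeakTrain([1000 / RATE]))
        assert out.t_peaks[0] == pytest.approx(1000 / RATE)

    def test_displaced_8ms_lands_on_true_maximum(self):
        sig = self._pulse_signal(1000)
        out = refine_peaks_local(sig, PeakTrain([(1000 + 2) / RATE]))  # 8 ms = 2 samples
        assert out.t_peaks[0] == pytest.approx(1000 / RATE)

    def test_iterative_reach_beyond_single_window(self):
        # maximum ~15 ms away, reachable only via an intermediate rise
        sig = self._pulse_signal(1000)
        start = 1000 - 4  # 16 ms early, monotone rise leads inward
        out = refine_peaks_local(sig, PeakTrain([start / RATE]))
        # oracle: exhaustive search within +-0.03 s
        lo, hi = start - int(0.03 * RATE), start + int(0.03 * RATE) + 1
        oracle = lo + int(np.argmax(sig.values[lo:hi]))
        assert out.t_peaks[0] == pytest.approx(oracle / RATE)

    def test_duplicates_collapse(self):
        sig = self._pulse_signal(1000)
        out = refine_peaks_local(sig, PeakTrain([998 / RATE, 1002 / RATE]))
        assert len(out) == 1


class TestHrFromPeaks:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([0.0, 0.4, 0.8], [150.0, 150.0]),
            ([0.0, 1.0, 2.0], [60.0, 60.0]),
            ([0.0, 0.5, 0.9], [120.0, 150.0]),
        ],
    )
    def test_known_values(self, peaks, expected):
        hr = hr_from_peaks(PeakTrain(peaks))
        np.testing.assert_allclose(hr.hr, expected)

    def test_timestamp_is_later_peak(self):
        hr = hr_from_peaks(PeakTrain([0.0, 0.4, 0.9]))
        np.testing.assert_allclose(hr.t, [0.4, 0.9])

    def test_exactness_against_direct_differencing(self, rng):
        t = np.cumsum(rng.uniform(0.3, 0.6, 200))
        hr = hr_from_peaks(PeakTrain(t))
        np.testing.assert_array_equal(hr.hr, 60.0 / np.diff(t))

    def test_fewer_than_two_peaks_empty(self):
        assert len(hr_from_peaks(PeakTrain([1.0]))) == 0


def _uniform_train(n=200, gap=0.4):
    return PeakTrain(np.arange(n) * gap)


class TestMedianBeatCorrection:
    def test_uniform_unchanged(self):
        hr = hr_from_peaks(_uniform_train())
        out = median_beat_correction(hr)
        np.testing.assert_array_equal(out.hr, hr.hr)
        assert (out.flags == FLAG_OK).all()

    def test_missing_beat_rejected_and_interpolated(self):
        t = np.delete(np.arange(200) * 0.4, 100)  # one doubled gap -> 75 bpm
        hr = hr_from_peaks(PeakTrain(t))
        bad = int(np.argmin(hr.hr))
        assert hr.hr[bad] == pytest.approx(75.0)
        out = median_beat_correction(hr)
        assert out.flags[bad] == FLAG_MEDIAN_REJECT
        assert out.hr[bad] == pytest.approx(150.0, abs=0.5)

    def test_extra_beat_rejected(self):
        t = np.sort(np.append(np.arange(200) * 0.4, 100 * 0.4 + 0.2))  # halved gap
        hr = hr_from_peaks(PeakTrain(t))
        out = median_beat_correction(hr)
        assert (out.flags[hr.hr > 250] == FLAG_MEDIAN_REJECT).all()
        assert np.allclose(out.hr, 150.0, atol=0.5)

    def test_accepted_samples_never_altered(self, rng):
        t = np.cumsum(rng.uniform(0.35, 0.45, 300))
        hr = hr_from_peaks(PeakTrain(t))
        out = median_beat_correction(hr)
        ok = out.flags == FLAG_OK
        np.testing.assert_array_equal(out.hr[ok], hr.hr[ok])

    def test_idempotent(self):
        t = np.delete(np.arange(200) * 0.4, [50, 130])
        hr = hr_from_peaks(PeakTrain(t))
        once = median_beat_correction(hr)
        twice = median_beat_correction(once)
        np.testing.assert_array_equal(once.hr, twice.hr)

    def test_parameter_validation(self):
        hr = hr_from_peaks(_uniform_train(10))
        with pytest.raises(ValueError):
            median_beat_correction(hr, fw=4)
        with pytest.raises(ValueError):
            median_beat_correction(hr, at=1.0)


class TestDetectShiftedBeats:
    def test_uniform_train_clean(self):
        hr = hr_from_peaks(_uniform_train())
        assert len(detect_shifted_beats(hr)) == 0

    def test_early_beat_signature_flagged(self):
        # one beat 0.1 s early in a 0.4 s train: HR ... 150, 200, 120, 150 ...
        t = np.arange(50) * 0.4
        t[25] -= 0.1
        hr = hr_from_peaks(PeakTrain(t))
        idx = detect_shifted_beats(hr)
        assert len(idx) == 1
        k = idx[0]
        d = np.diff(hr.hr)
        assert d[k] > 15 and d[k + 1] < -25 and d[k + 2] > 15

    def test_smooth_variation_not_flagged(self):
        # +-10 bpm sinusoid keeps successive differences under 15 bpm
        t = [0.0]
        while t[-1] < 120.0:
            t.append(t[-1] + 60.0 / (150.0 + 10.0 * np.sin(0.5 * t[-1])))
        hr = hr_from_peaks(PeakTrain(np.array(t)))
        assert np.abs(np.diff(hr.hr)).max() < 15.0
        assert len(detect_shifted_beats(hr)) == 0


class TestComputeSqi:
    def test_clean_recording_nearly_all_good(self):
        spec = synth.SynthSpec(seed=5, duration=600.0,
                               hr_profile=("sinusoidal", 130.0, 8.0, 6.0),
                               noise_snr_db=20.0)
        e = synth.synth_ecg(spec)
        hr, sqi, peaks = run_hr_pipeline(e.ecg)
        assert sqi.mean() >= 0.99
        good_time = np.sum(np.diff(peaks.t_peaks)[sqi])
        assert abs(good_time - spec.duration) / spec.duration < 0.02

    def test_short_clean_recording_below_5s_all_zero(self):
        hr = hr_from_peaks(_uniform_train(11))  # 4 s of beats
        sqi = compute_sqi(hr, _uniform_train(11))
        assert not sqi.any()

    def test_long_peak_gap_zeroed(self):
        t = np.concatenate([np.arange(50) * 0.4, 23.0 + np.arange(50) * 0.4])
        peaks = PeakTrain(t)
        hr = median_beat_correction(hr_from_peaks(peaks))
        sqi = compute_sqi(hr, peaks)
        gap_sample = 49  # spans the 3.4 s silence
        assert not sqi[gap_sample]

    @given(st.integers(0, 2**31 - 1))
    def test_surviving_good_regions_span_at_least_5s(self, seed):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.3, 0.6, 150))
        peaks = PeakTrain(t)
        hr = hr_from_peaks(peaks)
        hr.flags = np.where(rng.random(len(hr)) < 0.3, FLAG_MEDIAN_REJECT, FLAG_OK)
        sqi = compute_sqi(hr, peaks)
        runs = np.flatnonzero(np.diff(np.concatenate([[0], sqi.view(np.int8), [0]])))
        for a, b in zip(runs[::2], runs[1::2]):
            assert t[b] - t[a] >= 5.0 - 1e-9

    def test_noise_injection_never_increases_good_time(self):
        base = dict(seed=8, duration=600.0, hr_profile=("sinusoidal", 130.0, 8.0, 6.0),
                    noise_snr_db=18.0)
        clean = synth.synth_ecg(synth.SynthSpec(**base))
        noisy = synth.synth_ecg(synth.SynthSpec(**base, scramble_intervals=[(200.0, 230.0)]))
        _, sqi_c, pk_c = run_hr_pipeline(clean.ecg)
        _, sqi_n, pk_n = run_hr_pipeline(noisy.ecg)
        good_c = np.sum(np.diff(pk_c.t_peaks)[sqi_c])
        good_n = np.sum(np.diff(pk_n.t_peaks)[sqi_n])
        assert good_n <= good_c


class TestPipeline:
    def test_empty_input_empty_output(self):
        raw = TimedSamples(np.empty(0), np.empty(0), "ecg")
        hr, sqi, peaks = run_hr_pipeline(raw)
        assert len(hr) == 0 and len(sqi) == 0 and len(peaks) == 0

    def test_deterministic(self):
        spec = synth.SynthSpec(seed=11, duration=60.0,
                               hr_profile=("constant", 150.0), noise_snr_db=15.0)
        a = run_hr_pipeline(synth.synth_ecg(spec).ecg)
        b = run_hr_pipeline(synth.synth_ecg(spec).ecg)
        np.testing.assert_array_equal(a[0].hr, b[0].hr)
        np.testing.assert_array_equal(a[1], b[1])

    def test_simulator_mean_rate_recovered_precisely(self):
        # desk-scale analogue of a uniform 150 bpm simulator recording
        spec = synth.SynthSpec(seed=12, duration=600.0, hr_profile=("constant", 150.0))
        e = synth.synth_ecg(spec)
        hr, sqi, peaks = run_hr_pipeline(e.ecg)
        mean_hr = 60.0 / np.mean(np.diff(peaks.t_peaks))
        assert mean_hr == pytest.approx(150.0, abs=0.01)
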