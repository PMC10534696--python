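"""Locating, decoding, matching and clock correction of sync signals."""

import numpy as np
import pytest

from egosync import sync_codec
from egosync.sync_detect import (
    FrameStats,
    SyncDetection,
    apply_clock_correction,
    coarse_candidates,
    decode_bits,
    detect_lux,
    detect_video,
    frame_signals,
    match_and_align,
    ncc_locate,
    ncc_response,
    relative_clock_speed,
)
from egosync.synth import SynthSpec, synth_sync_streams
from egosync.timebase import TimedSamples, UniformSignal


def ncc_oracle(x, template):
    """Brute-force sliding-window normalized cross-correlation."""
    x = np.asarray(x, float)
    t = np.asarray(template, float)
    tc = t - t.mean()
    out = np.zeros(len(x) - len(t) + 1)
    for i in range(len(out)):
        w = x[i:i + len(t)]
        wc = w - w.mean()
        den = np.sqrt((wc @ wc) * (tc @ tc))
        out[i] = (wc @ tc) / den if den > 0 else 0.0
    return out


class TestFrameSignals:
    def test_pure_green_frame(self):
        stats = FrameStats([0.0], [[0.0, 1.0, 0.0]])
        intensity, greenness = frame_signals(stats)
        assert greenness.values[0] == pytest.approx(1.0)
        assert intensity.values[0] == pytest.approx(1.0 / 3.0)

    def test_white_frame(self):
        stats = FrameStats([0.0], [[1.0, 1.0, 1.0]])
        intensity, greenness = frame_signals(stats)
        assert greenness.values[0] == 0.0
        assert intensity.values[0] == pytest.approx(1.0)

    def test_rendered_waveform_green_only_at_end(self):
        code = sync_codec.make_code(3, 7, 1)
        rate = 30.0
        t = np.arange(int(12 * rate)) / rate
        lvl = sync_codec.waveform_level(code, t)
        rgb = np.zeros((len(t), 3))
        rgb[lvl == 1] = 1.0
        rgb[lvl == 2] = (0.0, 1.0, 0.0)
        _, greenness = frame_signals(FrameStats(t, rgb))
        nz = np.flatnonzero(greenness.values)
        assert t[nz[0]] >= 8.8 - 1e-9
        assert t[nz[-1]] < 9.8


class TestCoarseCandidates:
    def _greenness(self, onsets, duration=60.0, rate=30.0):
        t = np.arange(int(duration * rate)) / rate
        g = np.zeros(len(t))
        for onset in onsets:  # waveform start; green at +8.8 .. +9.8 s
            g[(t >= onset + 8.8) & (t < onset + 9.8)] = 1.0
        return UniformSignal(g, rate=rate)

    def test_zero_greenness_no_candidates(self):
        assert len(coarse_candidates(self._greenness([]))) == 0

    def test_single_waveform_matches_bruteforce_argmax(self):
        sig = self._greenness([10.0])
        cands = coarse_candidates(sig)
        assert len(cands) == 1
        # independent filter response: zero pad 1 s, -1 for 2 s, +1 for 1 s
        kernel = np.concatenate([np.zeros(30), -np.ones(60), np.ones(30)])
        resp = np.array([
            kernel @ sig.values[i:i + len(kernel)]
            for i in range(len(sig.values) - len(kernel) + 1)
        ])
        assert cands[0] == np.argmax(resp)

    def test_min_distance_collapses_near_duplicates(self):
        far = coarse_candidates(self._greenness([5.0, 25.0]))
        near = coarse_candidates(self._greenness([5.0, 15.0]))
        assert len(far) == 2
        assert len(near) == 1  # 500-frame (16.7 s) minimum peak spacing


class TestNCC:
    def test_matches_bruteforce_oracle_on_random_signals(self, rng):
        template = sync_codec.build_template(100.0).values
        worst = 0.0
        for _ in range(10):
            n = int(rng.integers(len(template) + 1, 10_000))
            x = rng.normal(0, 1, n)
            got = ncc_response(x, template)
            want = ncc_oracle(x, template)
            worst = max(worst, np.abs(got - want).max())
        assert worst < 1e-9

    def test_noiseless_location_exact_and_score_matches_oracle(self):
        code = sync_codec.make_code(5, 11, 2)
        rate = 500.0
        wf = sync_codec.build_waveform(code, rate).values
        x = np.concatenate([np.zeros(int(3 * rate)), wf, np.zeros(int(3 * rate))])
        sig = UniformSignal(x, rate=rate)
        dets = ncc_locate(sig)
        assert len(dets) == 1
        onset, score = dets[0]
        assert abs(onset - (3.0 + 3.2)) <= 1.0 / rate + 1e-9
        template = sync_codec.build_template(rate).values
        oracle = ncc_oracle(x, template)
        assert score == pytest.approx(oracle.max(), abs=1e-9)

    def test_pure_noise_streams_yield_no_detections(self):
        rate = 500.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = (rng.random(int(30 * rate)) > 0.5).astype(float)
            assert ncc_locate(UniformSignal(x, rate=rate)) == []

    @pytest.mark.parametrize("corrupt_at", [0.5, 3.5, 5.0, 8.0])
    def test_survives_400ms_complemented_segment(self, corrupt_at):
        code = sync_codec.make_code(13, 19, 3)
        rate = 500.0
        wf = sync_codec.build_waveform(code, rate).values.copy()
        i0, i1 = int(corrupt_at * rate), int((corrupt_at + 0.4) * rate)
        wf[i0:i1] = 1.0 - wf[i0:i1]
        x = np.concatenate([np.zeros(int(3 * rate)), wf, np.zeros(int(3 * rate))])
        dets = ncc_locate(UniformSignal(x, rate=rate))
        assert len(dets) == 1
        assert abs(dets[0][0] - 6.2) < 0.05


class TestDecodeBits:
    def _lux_signal(self, code, rate=500.0):
        wf = sync_codec.build_waveform(code, rate).values
        binary = (wf >= 0.5).astype(float)
        return UniformSignal(binary, rate=rate)

    def test_exact_round_trip_binary(self):
        code = sync_codec.make_code(13, 19, 3)
        bits, ok = decode_bits(self._lux_signal(code), onset=3.2,
                               threshold=0.5, mode="median")
        assert ok
        assert bits == code.bits

    def test_dim_white_level_still_decodes(self):
        # white recorded at 0.6 still exceeds the 0.3 video threshold
        code = sync_codec.make_code(13, 19, 3)
        sig = self._lux_signal(code)
        sig.values *= 0.6
        bits, ok = decode_bits(sig, onset=3.2, threshold=0.3, mode="mean")
        assert ok and bits == code.bits

    def test_all_low_window_decodes_zero(self):
        sig = UniformSignal(np.zeros(10000), rate=500.0)
        bits, ok = decode_bits(sig, onset=3.2)
        assert ok and bits == (0,) * 10

    def test_window_beyond_bounds_flags_failure(self):
        sig = UniformSignal(np.zeros(100), rate=500.0)
        bits, ok = decode_bits(sig, onset=0.0)
        assert not ok and bits is None


class TestEndToEnd:
    def test_synthetic_lux_and_video_recover_code_and_onset(self):
        code = sync_codec.make_code(22, 6, 0)
        spec = SynthSpec(seed=9, duration=40.0, codes=[(code, 12.0)])
        streams = synth_sync_streams(spec)
        lux_dets = detect_lux(streams.lux)
        vid_dets = detect_video(streams.frames)
        assert len(lux_dets) == len(vid_dets) == 1
        assert lux_dets[0].bits == code.bits and lux_dets[0].valid
        assert vid_dets[0].bits == code.bits and vid_dets[0].valid
        assert abs(lux_dets[0].onset_time - streams.lux_onsets[0]) < 0.01
        assert abs(vid_dets[0].onset_time - streams.video_onsets[0]) < 0.05

    def test_stream_without_codes_has_no_detections(self):
        spec = SynthSpec(seed=10, duration=30.0, codes=[])
        streams = synth_sync_streams(spec)
        assert detect_lux(streams.lux) == []
        assert detect_video(streams.frames) == []


def _det(stream, onset, bits_str):
    day3, hour5, counter2, valid = sync_codec.decode_fields(bits_str)
    return SyncDetection(stream_id=stream, onset_time=onset, ncc_score=0.9,
                         bits=tuple(int(b) for b in bits_str),
                         day3=day3, hour5=hour5, counter2=counter2, valid=valid)


class TestMatchAndAlign:
    def test_four_streams_one_group_aligned_to_zero(self):
        x = "1011001111"
        dets = {f"s{i}": [_det(f"s{i}", 10.0 + i, x)] for i in range(4)}
        res = match_and_align(dets)
        assert len(res.groups) == 1
        for i in range(4):
            onset = dets[f"s{i}"][0].onset_time
            assert res.offsets[f"s{i}"] == onset  # aligned time = t - offset = 0

    def test_unshared_code_reported_unmatched(self):
        x, y = "1011001111", "0000000001"
        dets = {
            "camera": [_det("camera", 5.0, x), _det("camera", 40.0, y)],
            "sensor": [_det("sensor", 7.0, x)],
        }
        res = match_and_align(dets)
        assert len(res.groups) == 1
        assert res.groups[0]["code"] == int(x, 2)
        assert [d.decimal for d in res.unmatched] == [int(y, 2)]

    def test_duplicate_code_disambiguated_by_order(self):
        x = "0100000001"
        dets = {
            "a": [_det("a", 5.0, x), _det("a", 50.0, x)],
            "b": [_det("b", 8.0, x), _det("b", 53.0, x)],
        }
        res = match_and_align(dets)
        assert len(res.groups) == 2
        first, second = res.groups
        assert first["members"]["a"].onset_time == 5.0
        assert first["members"]["b"].onset_time == 8.0
        assert second["members"]["a"].onset_time == 50.0
        # each stream aligns on its latest matched sync
        assert res.offsets == {"a": 50.0, "b": 53.0}

    def test_latest_sync_defines_time_zero(self):
        x, y = "1011001111", "0000000001"
        dets = {
            "a": [_det("a", 5.0, x), _det("a", 60.0, y)],
            "b": [_det("b", 6.0, x), _det("b", 61.0, y)],
        }
        res = match_and_align(dets)
        assert res.offsets == {"a": 60.0, "b": 61.0}


class TestClockCorrection:
    def test_direction_maps_device_ahead_to_real_time(self):
        assert apply_clock_correction(np.array([1000.1]))[0] == pytest.approx(1000.0, abs=1e-3)

    def test_factor_one_is_identity(self):
        t = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(apply_clock_correction(t, 1.0), t)

    def test_corrects_drifted_peak_train_gaps(self):
        device = np.arange(1000) * (0.4 / 0.9999)
        corrected = apply_clock_correction(device)
        assert np.allclose(np.diff(corrected), 0.4, atol=1e-12)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            apply_clock_correction(np.array([1.0]), 0.0)


class TestRelativeClockSpeed:
    def test_recovers_injected_factor(self):
        factor = 0.9999
        n = int(2 * 3600 / 0.4)  # 2 h of 150 bpm beats
        device_times = np.arange(n) * (0.4 / factor)
        speeds, overall = relative_clock_speed(device_times, 0.4)
        assert len(speeds) >= 3  # half-hour batches
        assert overall == pytest.approx(factor, abs=1e-6)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            relative_clock_speed([1.0], 0.4)
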