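"""Spectrogram, template scoring, peak picking, and selection-table I/O."""

import numpy as np
import pytest

from pamharvest.audio import AudioRecording
from pamharvest.detection import (
    SelectionTableError,
    Spectrogram,
    StftParams,
    Template,
    build_template,
    compute_spectrogram,
    detect,
    DetectionEvent,
    read_selection_table,
    score_series,
    write_selection_table,
)
from pamharvest.synthetic import GunshotSpec, SceneSpec, render_scene, synth_gunshot

SR = 8000


def _rec(samples):
    return AudioRecording(samples=np.asarray(samples, dtype=float),
                          sample_rate_hz=SR, sensor_id="test")


class TestSpectrogram:
    def test_exact_frame_count(self):
        spec = compute_spectrogram(_rec(np.zeros(8000)), StftParams(256, 64))
        assert spec.n_frames == (8000 - 256) // 64 + 1 == 122

    def test_silence_sits_at_constant_log_floor(self):
        spec = compute_spectrogram(_rec(np.zeros(4000)))
        assert np.ptp(spec.magnitude) == 0.0

    def test_sine_peaks_at_nearest_bin(self):
        t = np.arange(SR) / SR
        spec = compute_spectrogram(_rec(np.sin(2 * np.pi * 1000 * t)))
        expected_bin = np.argmin(np.abs(spec.freqs_hz - 1000.0))
        assert np.all(spec.magnitude.argmax(axis=1) == expected_bin)

    def test_audio_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than one analysis window"):
            compute_spectrogram(_rec(np.zeros(100)), StftParams(256, 64))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            StftParams(window_samples=64, hop_samples=128)


class TestTemplate:
    def test_single_clip_template_is_its_normalised_patch(self, gun, stft_params):
        clip = synth_gunshot(gun, 150.0, SR)
        tmpl = build_template([clip], SR, gun.duration_s,
                              (gun.band_low_hz, gun.band_high_hz), stft_params)
        assert tmpl.patch.mean() == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(tmpl.patch) == pytest.approx(1.0, abs=1e-9)

    def test_averaging_identical_clips_is_idempotent(self, gun, stft_params):
        clip = synth_gunshot(gun, 150.0, SR)
        one = build_template([clip], SR, gun.duration_s,
                             (gun.band_low_hz, gun.band_high_hz), stft_params)
        two = build_template([clip, clip.copy()], SR, gun.duration_s,
                             (gun.band_low_hz, gun.band_high_hz), stft_params)
        np.testing.assert_allclose(one.patch, two.patch, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalisation_contract_for_arbitrary_clips(self, seed, stft_params):
        rng = np.random.default_rng(seed)
        clips = [rng.normal(0, 0.1, 3200) for _ in range(rng.integers(1, 5))]
        tmpl = build_template(clips, SR, 0.4, (200.0, 3000.0), stft_params)
        assert abs(float(np.linalg.norm(tmpl.patch)) - 1.0) < 1e-9

    def test_empty_clip_list_rejected(self, stft_params):
        with pytest.raises(ValueError, match="at least one clip"):
            build_template([], SR, 0.4, (200.0, 3000.0), stft_params)


class TestScoreSeries:
    def test_self_correlation_scores_one(self, gun, template, stft_params):
        scene = SceneSpec(duration_s=3.0, noise_rms=0.0, events=[(1.0, 150.0)], seed=0)
        audio, _ = render_scene(scene, gun)
        clip = audio.samples[SR:SR + 3200]
        tmpl = build_template([clip], SR, gun.duration_s,
                              (gun.band_low_hz, gun.band_high_hz), stft_params)
        spec = compute_spectrogram(_rec(clip), stft_params)
        scores = score_series(spec, tmpl)
        assert scores.max() == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_null_scores_near_zero(self, template, stft_params):
        # >1000 alignments of the template against pure noise
        rng = np.random.default_rng(12)
        audio = _rec(rng.normal(0, 0.01, SR * 10))
        spec = compute_spectrogram(audio, stft_params)
        scores = score_series(spec, template)
        assert scores.size > 1000
        assert scores.mean() < 0.1

    def test_constant_spectrogram_scores_zero_not_nan(self, template, stft_params):
        spec = compute_spectrogram(_rec(np.zeros(SR * 2)), stft_params)
        scores = score_series(spec, template)
        assert np.all(scores == 0.0)
        assert not np.any(np.isnan(scores))

    def test_band_mismatch_rejected(self, gun, stft_params):
        clip = synth_gunshot(gun, 150.0, SR)
        tmpl = build_template([clip], SR, gun.duration_s, (200.0, 3000.0), stft_params)
        narrow = Spectrogram(
            magnitude=np.zeros((100, 10)),
            frame_times_s=np.arange(100) * 0.008,
            freqs_hz=np.linspace(200, 500, 10),
            stft_params=stft_params,
        )
        with pytest.raises(ValueError, match="band mismatch"):
            score_series(narrow, tmpl)


def _triangle(center, width, height, n=500, dt=0.008):
    scores = np.zeros(n)
    times = np.arange(n) * dt
    scores[center - width:center + width + 1] = height * (
        1 - np.abs(np.arange(-width, width + 1)) / (width + 1))
    return scores, times


class TestDetect:
    def test_all_scores_below_threshold_gives_nothing(self):
        scores, times = _triangle(250, 20, 0.3)
        assert detect(scores, times, threshold=0.4) == []

    def test_single_isolated_peak(self):
        scores, times = _triangle(250, 20, 0.8)
        events = detect(scores, times, threshold=0.4)
        assert len(events) == 1
        assert events[0].peak_score == pytest.approx(0.8)
        assert events[0].n_gunshots == 1

    def test_recovers_all_injected_shots(self, detected_scene):
        _, _, truth, detections = detected_scene
        assert len(detections) == len(truth) == 10
        assert all(ev.n_gunshots == 1 for ev in detections)

    def test_rapid_volley_merges_into_one_window(self):
        scores = np.zeros(1000)
        times = np.arange(1000) * 0.008
        for c in (300, 340, 380):  # 0.32 s apart, inside the 0.5 s gap
            scores[c - 10:c + 11] = np.maximum(
                scores[c - 10:c + 11],
                0.7 * (1 - np.abs(np.arange(-10, 11)) / 11))
        events = detect(scores, times, threshold=0.4, peak_refractory_s=0.2)
        assert len(events) == 1
        assert events[0].n_gunshots == 3  # count conservation over the cluster

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        scores = np.clip(rng.random(5000) ** 3, 0, 1)
        times = np.arange(5000) * 0.008
        counts = [sum(e.n_gunshots for e in detect(scores, times, threshold=th))
                  for th in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_emitted_scores_exceed_threshold(self, detected_scene):
        _, _, _, detections = detected_scene
        assert all(0.4 < ev.peak_score <= 1.0 for ev in detections)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect(np.zeros(10), np.arange(10.0), threshold=1.5)


class TestSelectionTables:
    def _events(self):
        return [
            DetectionEvent("s1", 1.0 + i, 1.4 + i, 0.5 + 0.05 * i, 1 + i, 200.0, 3000.0)
            for i in range(5)
        ]

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "sel.txt"
        events = self._events()
        write_selection_table(events, path)
        back = read_selection_table(path)
        assert len(back) == 5
        for a, b in zip(events, back):
            assert b.begin_s == pytest.approx(a.begin_s, abs=1e-6)
            assert b.end_s == pytest.approx(a.end_s, abs=1e-6)
            assert b.low_hz == a.low_hz and b.high_hz == a.high_hz
            assert b.peak_score == pytest.approx(a.peak_score, abs=1e-6)
            assert b.n_gunshots == a.n_gunshots

    def test_empty_table_round_trips(self, tmp_path):
        path = tmp_path / "empty.txt"
        write_selection_table([], path)
        assert read_selection_table(path) == []

    def test_missing_mandatory_column_is_named(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Selection\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\n")
        with pytest.raises(SelectionTableError, match=r"Begin Time \(s\)"):
            read_selection_table(path)

    def test_comma_decimals_rejected(self, tmp_path):
        path = tmp_path / "commas.txt"
        path.write_text(
            "Selection\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\n"
            "1\t1,5\t2,0\t200\t3000\n"
        )
        with pytest.raises(SelectionTableError, match="not numeric"):
            read_selection_table(path)
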