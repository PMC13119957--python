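"""I/O, resampling, normalization and windowing."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modrepair.signal_io import (AlignmentError, ModalityStream, Recording,
                                 channel_stats, make_windows, read_recording,
                                 resample, window_count, write_recording,
                                 zscore)


def _stream(samples, rate=64.0, name="s"):
    return ModalityStream(name, rate, np.asarray(samples, dtype=float))


class TestReadWrite:
    def test_round_trip_csv_is_bit_identical(self, tiny_recording, tmp_path):
        manifest = write_recording(tiny_recording, tmp_path, fmt="csv")
        back = read_recording(manifest)
        assert back.subject_id == tiny_recording.subject_id
        for m, s in tiny_recording.streams.items():
            np.testing.assert_array_equal(back.streams[m].samples, s.samples)
            assert back.streams[m].rate == s.rate
        np.testing.assert_array_equal(back.labels, tiny_recording.labels)

    def test_round_trip_h5(self, tiny_recording, tmp_path):
        manifest = write_recording(tiny_recording, tmp_path, fmt="h5")
        back = read_recording(manifest)
        for m, s in tiny_recording.streams.items():
            np.testing.assert_array_equal(back.streams[m].samples, s.samples)

    def test_declared_shapes_load(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = Recording(
            "S9",
            {"a": _stream(rng.normal(size=(640, 2)), 64.0, "a"),
             "b": _stream(rng.normal(size=(1280, 1)), 128.0, "b")},
            labels=np.zeros(640, dtype=int), label_rate=64.0)
        back = read_recording(write_recording(rec, tmp_path))
        assert back.streams["a"].samples.shape == (640, 2)
        assert back.streams["b"].samples.shape == (1280, 1)

    def test_missing_file_names_modality(self, tiny_recording, tmp_path):
        manifest = write_recording(tiny_recording, tmp_path)
        (tmp_path / "eda.csv").unlink()
        with pytest.raises(FileNotFoundError, match="eda"):
            read_recording(manifest)

    def test_duplicate_modalities_rejected(self, tiny_recording, tmp_path):
        manifest = write_recording(tiny_recording, tmp_path)
        data = json.loads(manifest.read_text())
        data["modalities"].append(data["modalities"][0])
        manifest.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="duplicate"):
            read_recording(manifest)

    def test_non_finite_samples_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            _stream([[1.0], [np.nan]])


class TestResample:
    def test_same_rate_is_identity(self):
        s = _stream(np.random.default_rng(0).normal(size=(100, 2)))
        out = resample(s, 64.0)
        np.testing.assert_array_equal(out.samples, s.samples)

    def test_constant_stays_constant(self):
        s = _stream(np.full((400, 1), 3.0), rate=200.0)
        out = resample(s, 64.0)
        np.testing.assert_allclose(out.samples, 3.0)
        assert out.rate == 64.0

    def test_ramp_interpolates_midpoints(self):
        s = _stream(np.array([0.0, 1.0, 2.0, 3.0])[:, None], rate=4.0)
        out = resample(s, 8.0)
        # midpoints between consecutive samples appear
        np.testing.assert_allclose(out.samples[1, 0], 0.5)
        np.testing.assert_allclose(out.samples[3, 0], 1.5)

    @pytest.mark.parametrize("rate,target", [(64.0, 32.0), (200.0, 64.0),
                                             (10.0, 35.0)])
    def test_duration_preserved_within_one_sample(self, rate, target):
        s = _stream(np.zeros((int(rate * 7), 1)), rate=rate)
        out = resample(s, target)
        assert abs(out.duration - s.duration) <= 1.0 / target + 1e-9

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            resample(_stream(np.zeros((10, 1))), 0.0)


class TestZscore:
    def test_constant_channel_maps_to_zero(self):
        out = zscore(_stream(np.full((3, 1), 5.0)))
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_hand_computed_population_std(self):
        out = zscore(_stream(np.array([1.0, 2.0, 3.0])[:, None]))
        np.testing.assert_allclose(out.samples[:, 0],
                                   [-1.2247, 0.0, 1.2247], atol=1e-3)

    def test_moments_after_normalization(self, rng):
        out = zscore(_stream(rng.normal(3.0, 7.0, size=(500, 3))))
        np.testing.assert_allclose(out.samples.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.samples.std(axis=0), 1.0, atol=1e-6)

    def test_stored_stats_reuse_matches_self_normalization(self, rng):
        s = _stream(rng.normal(size=(200, 2)))
        np.testing.assert_array_equal(
            zscore(s, stats=channel_stats(s)).samples, zscore(s).samples)

    def test_idempotence(self, rng):
        s = _stream(rng.normal(2.0, 3.0, size=(300, 2)))
        once = zscore(s)
        twice = zscore(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-6)


class TestWindows:
    def _rec(self, n, rate=64.0, labels=None):
        samples = np.arange(n, dtype=float)[:, None]
        labels = np.zeros(n, dtype=int) if labels is None else labels
        return Recording("W", {"x": _stream(samples, rate, "x")},
                         labels, label_rate=rate)

    def test_single_exact_window(self):
        batch = make_windows(self._rec(640), 10.0, 0.5)
        assert batch.n_windows == 1

    def test_stride_formula(self):
        batch = make_windows(self._rec(1280), 10.0, 0.5)
        assert batch.n_windows == 3
        np.testing.assert_array_equal(batch.windows["x"][1, 0, 0], 320.0)
        np.testing.assert_array_equal(batch.windows["x"][2, 0, 0], 640.0)

    def test_majority_tie_breaks_to_smaller_label(self):
        labels = np.repeat([1, 0], 320)  # larger label first: tie in window
        batch = make_windows(self._rec(640, labels=labels), 10.0, 0.5)
        assert batch.labels[0] == 0

    def test_count_matches_brute_force_enumeration(self):
        for t, t_w, stride in [(640, 640, 320), (1280, 640, 320),
                               (1000, 64, 13), (65, 64, 64), (63, 64, 32)]:
            brute = len([s for s in range(0, t, 1)
                         if s % stride == 0 and s + t_w <= t])
            assert window_count(t, t_w, stride) == brute

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(t=st.integers(1, 3000), t_w=st.integers(1, 500),
           stride=st.integers(1, 400))
    def test_count_formula_property(self, t, t_w, stride):
        brute = sum(1 for s in range(0, max(t - t_w, 0) + 1, stride))
        assert window_count(t, t_w, stride) == (brute if t >= t_w else 0)

    def test_multirate_alignment(self, tiny_recording):
        batch = make_windows(tiny_recording, 10.0, 0.5)
        assert batch.windows["imu"].shape == (3, 640, 3)
        assert batch.windows["eda"].shape == (3, 320, 1)
        assert batch.presence.all()

    def test_too_short_stream_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            make_windows(self._rec(100), 10.0, 0.5)

    def test_inconsistent_durations_error(self):
        rec = Recording(
            "W", {"a": _stream(np.zeros((640, 1)), 64.0, "a"),
                  "b": _stream(np.zeros((900, 1)), 64.0, "b")},
            np.zeros(640, dtype=int), label_rate=64.0)
        with pytest.raises(AlignmentError):
            make_windows(rec, 10.0, 0.5)
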