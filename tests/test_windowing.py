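"""Frame-aligned windowing, RMS power, baseline normalization."""

import numpy as np
import pandas as pd
import pytest

import raseeg as rg
from raseeg.preprocessing import band_decompose
from raseeg.recording import EEGRecording
from raseeg.windowing import (align_frames, baseline_stats, nearest_sample,
                              normalize, window_rms)

FS = 500.0


def _recording(duration=5.0, baseline=1.0, n_chan=1, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    data = rng.standard_normal((n_chan, n))
    chans = tuple(f"ch{i}" for i in range(n_chan))
    return EEGRecording(chans, FS, data,
                        segments={"baseline": (0.0, baseline),
                                  "task_1": (baseline, duration)})


class TestAlignFrames:
    def test_30fps_500hz_geometry(self):
        rec = _recording(duration=2.0, baseline=1.0)
        ts = 1.0 + np.arange(30) / 30.0
        w = align_frames(ts, rec, segment="task_1")
        assert len(w) == 30
        assert set(np.unique(w.lengths)) <= {16, 17}
        # partition: contiguous, no gaps or overlaps, covers span
        assert np.array_equal(w.start_sample[1:], w.end_sample[:-1])
        assert w.lengths.sum() == w.end_sample[-1] - w.start_sample[0]

    def test_partition_brute_force(self):
        rec = _recording(duration=2.0, baseline=1.0)
        ts = 1.0 + np.sort(np.random.default_rng(1).uniform(0, 0.9, 25))
        w = align_frames(ts, rec, segment="task_1", min_samples=1)
        counts = np.zeros(rec.n_samples, dtype=int)
        for i in range(len(w)):
            counts[w.start_sample[i]:w.end_sample[i]] += 1
        covered = slice(w.start_sample[0], w.end_sample[-1])
        assert np.all(counts[covered] == 1)

    def test_mean_window_duration_33ms(self):
        rec = _recording(duration=11.0, baseline=1.0)
        ts = 1.0 + np.arange(300) / 30.0
        w = align_frames(ts, rec, segment="task_1")
        mean_ms = 1000.0 * np.mean(w.lengths) / FS
        assert mean_ms == pytest.approx(1000.0 / 30.0, abs=0.5)

    def test_single_frame_extends_to_segment_end(self):
        rec = _recording(duration=2.0, baseline=1.0)
        w = align_frames(np.array([1.5]), rec, segment="task_1")
        assert len(w) == 1
        assert w.end_sample[0] == rec.segment_slice("task_1").stop

    def test_frame_outside_span_raises_with_indices(self):
        rec = _recording(duration=2.0, baseline=1.0)
        with pytest.raises(ValueError, match="outside"):
            align_frames(np.array([1.5, 2.7]), rec, segment="task_1")

    def test_midpoint_tie_breaks_to_earlier_sample(self):
        # sample spacing 2 ms; timestamp exactly between samples 250 and 251
        assert nearest_sample([0.501], 0.0, FS)[0] == 250
        assert nearest_sample([0.5011], 0.0, FS)[0] == 251

    def test_recomputation_is_deterministic(self):
        rec = _recording(duration=3.0, baseline=1.0)
        ts = 1.0 + np.arange(50) / 30.0
        a = align_frames(ts, rec, segment="task_1")
        b = align_frames(ts, rec, segment="task_1")
        assert np.array_equal(a.start_sample, b.start_sample)
        assert np.array_equal(a.end_sample, b.end_sample)


class TestWindowRMS:
    def _decomp_windows(self, duration=3.0, seed=0):
        rec = _recording(duration=duration, baseline=1.0, seed=seed)
        decomp = band_decompose(rec)
        ts = 1.0 + np.arange(int((duration - 1.0) * 30) - 1) / 30.0
        w = align_frames(ts, rec, segment="task_1")
        return decomp, w

    def test_constant_window_rms_is_abs_value(self):
        rec = _recording(duration=2.0, baseline=1.0)
        decomp = band_decompose(rec)
        decomp.data[:] = -3.0
        ts = 1.0 + np.arange(10) / 30.0
        w = align_frames(ts, rec, segment="task_1")
        t = window_rms(decomp, w)
        assert np.allclose(t.values.to_numpy(), 3.0)

    def test_unit_sinusoid_whole_cycles(self):
        # 100 Hz within gamma; window of 50 samples = 10 whole cycles... use
        # direct construction: one window, 500 samples, 10 Hz -> 10 cycles
        rec = _recording(duration=2.0, baseline=1.0)
        decomp = band_decompose(rec)
        t = np.arange(decomp.n_samples) / FS
        decomp.data[:] = np.sin(2 * np.pi * 10.0 * t)
        w = align_frames(np.array([1.0]), rec, segment="task_1")  # 1 s window
        out = window_rms(decomp, w)
        assert np.allclose(out.values.to_numpy(), 1 / np.sqrt(2), atol=1e-6)

    def test_matches_elementwise_brute_force(self):
        decomp, w = self._decomp_windows(seed=3)
        table = window_rms(decomp, w)
        for i in (0, 5, len(w) - 1):
            s, e = w.start_sample[i], w.end_sample[i]
            for ch in decomp.channels:
                for b in decomp.bands:
                    direct = np.sqrt(np.mean(decomp.get(ch, b.name)[s:e] ** 2))
                    got = table.values.iloc[i][f"{ch}_{b.name}"]
                    assert got == pytest.approx(direct, rel=1e-12)

    def test_empty_window_set_raises(self):
        decomp, w = self._decomp_windows()
        from raseeg.windowing import WindowSet
        empty = WindowSet(*(np.empty(0, dtype=np.int64) for _ in range(3)),
                          np.empty(0), np.empty(0, dtype=bool))
        with pytest.raises(ValueError):
            window_rms(decomp, empty)


class TestBaseline:
    def test_stationary_noise_matches_process_rms(self):
        rec = _recording(duration=60.0, baseline=59.0, seed=5)
        decomp = band_decompose(rec)
        stats = baseline_stats(decomp)
        # long-run oracle: RMS of the full band-filtered baseline stream
        sl = decomp.segment_slice("baseline")
        for b in decomp.bands:
            process_rms = np.sqrt(np.mean(decomp.get("ch0", b.name)[sl] ** 2))
            got = stats.means[f"ch0_{b.name}"]
            # windowed mean-of-RMS sits below the process RMS (Jensen);
            # the gap grows as the band's correlation time approaches the
            # ~33 ms window (about 20% for delta, ~3% for gamma)
            assert 0.75 * process_rms <= got <= process_rms * 1.001

    def test_linearity_in_amplitude(self):
        rec = _recording(duration=4.0, baseline=3.0, seed=6)
        d1 = band_decompose(rec)
        d2 = band_decompose(rec.with_data(2.0 * rec.data))
        s1, s2 = baseline_stats(d1), baseline_stats(d2)
        assert np.allclose(2.0 * s1.means, s2.means, rtol=1e-9)

    def test_zero_baseline_raises_division_guard(self):
        rec = _recording(duration=2.0, baseline=1.0)
        decomp = band_decompose(rec)
        decomp.data[:] = 0.0
        with pytest.raises(ValueError):
            baseline_stats(decomp)


class TestNormalize:
    def _table_and_stats(self):
        rec = _recording(duration=3.0, baseline=1.0, seed=7)
        decomp = band_decompose(rec)
        ts = 1.0 + np.arange(45) / 30.0
        w = align_frames(ts, rec, segment="task_1")
        return window_rms(decomp, w), baseline_stats(decomp)

    def test_window_at_baseline_mean_maps_to_one(self):
        raw, stats = self._table_and_stats()
        flat = raw.values.copy()
        flat.iloc[0] = stats.means[flat.columns].to_numpy()
        flat.iloc[1] = 2.0 * stats.means[flat.columns].to_numpy()
        from raseeg.windowing import BandPowerTable
        table = BandPowerTable(flat, raw.meta, raw.channels, raw.bands)
        normed = normalize(table, stats)
        assert np.allclose(normed.values.iloc[0], 1.0)
        assert np.allclose(normed.values.iloc[1], 2.0)

    def test_round_trip_recovers_raw(self):
        raw, stats = self._table_and_stats()
        normed = normalize(raw, stats)
        back = normed.values * stats.means[normed.values.columns]
        assert np.allclose(back.to_numpy(), raw.values.to_numpy(), rtol=1e-12)

    def test_double_normalization_rejected(self):
        raw, stats = self._table_and_stats()
        normed = normalize(raw, stats)
        with pytest.raises(ValueError):
            normalize(normed, stats)

    def test_log_ratio_option(self):
        raw, stats = self._table_and_stats()
        a = normalize(raw, stats)
        b = normalize(raw, stats, method="log")
        assert np.allclose(np.log(a.values.to_numpy()), b.values.to_numpy(),
                           atol=1e-12)

    def test_row_count_matches_windows(self, small_cohort, small_table):
        n_frames = sum(len(s) for p in small_cohort.participants
                       for s in p.schedules.values())
        assert len(small_table.values) == n_frames
        assert len(small_table.meta) == len(small_table.values)
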