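"""Synthetic cohort generator: schedules, determinism, cohort structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raseeg as rg
from raseeg.synthetic import _band_calibration


TINY = dict(n_participants=2, tasks_per_participant=1, frames_per_task=60,
            baseline_duration=2.0, montage=("O1", "O2"))


class TestErrorSchedule:
    def test_zero_rate_gives_all_false(self):
        s = rg.generate_error_schedule(1000, 0.0, 30, seed=1)
        assert not s.labels.any()

    def test_study_scale_prevalence(self):
        # full study frame count; realized fraction close to 17.1%
        s = rg.generate_error_schedule(368043, 0.171, 30, seed=5)
        assert abs(s.error_fraction - 0.171) < 0.01

    def test_mean_prevalence_over_seeds(self):
        fracs = [rg.generate_error_schedule(20000, 0.171, 30, seed=s)
                 .error_fraction for s in range(100)]
        assert abs(np.mean(fracs) - 0.171) < 0.005

    def test_rerun_is_exact_oracle(self):
        a = rg.generate_error_schedule(100, 0.5, 1, seed=9)
        b = rg.generate_error_schedule(100, 0.5, 1, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.error_fraction == b.error_fraction

    def test_timestamps_strictly_increasing_and_at_frame_rate(self):
        s = rg.generate_error_schedule(90, 0.2, 5, seed=0, frame_rate=30.0,
                                       t_start=10.0)
        assert np.all(np.diff(s.timestamps) > 0)
        assert s.timestamps[0] == pytest.approx(10.0)
        assert np.allclose(np.diff(s.timestamps), 1 / 30.0)

    @pytest.mark.parametrize("kwargs", [
        dict(n_frames=0, target_error_rate=0.1, mean_error_run=5),
        dict(n_frames=10, target_error_rate=1.0, mean_error_run=5),
        dict(n_frames=10, target_error_rate=0.1, mean_error_run=0.5),
    ])
    def test_invalid_configuration_raises(self, kwargs):
        with pytest.raises(ValueError):
            rg.generate_error_schedule(seed=0, **kwargs)

    @given(n=st.integers(1, 500), rate=st.floats(0.0, 0.9),
           run=st.floats(1.0, 20.0), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_schedule_shape_properties(self, n, rate, run, seed):
        s = rg.generate_error_schedule(n, rate, run, seed)
        assert len(s) == n and s.labels.dtype == bool
        if rate == 0.0:
            assert not s.labels.any()


class TestSynthesizeEEG:
    def test_same_seed_bitwise_identical(self):
        cfg = rg.SimulationConfig(seed=3, **TINY)
        a = rg.generate_cohort(cfg)
        b = rg.generate_cohort(cfg)
        for pa, pb in zip(a.participants, b.participants):
            assert np.array_equal(pa.recording.data, pb.recording.data)
            for t in pa.schedules:
                assert np.array_equal(pa.schedules[t].labels,
                                      pb.schedules[t].labels)

    def test_different_seeds_differ(self):
        a = rg.generate_cohort(rg.SimulationConfig(seed=3, **TINY))
        b = rg.generate_cohort(rg.SimulationConfig(seed=4, **TINY))
        assert not np.array_equal(a.participants[0].recording.data,
                                  b.participants[0].recording.data)

    def test_segments_cover_schedules(self):
        cfg = rg.SimulationConfig(seed=1, tasks_per_participant=2,
                                  n_participants=1, frames_per_task=60,
                                  baseline_duration=2.0,
                                  montage=("O1", "O2"))
        bundle = rg.generate_cohort(cfg)
        p = bundle.participants[0]
        for task, sched in p.schedules.items():
            a, b = p.recording.segment_bounds(task)
            assert a - 1e-9 <= sched.timestamps[0]
            assert sched.timestamps[-1] <= b + 1e-9

    def test_unknown_effect_channel_or_band_rejected(self):
        with pytest.raises(ValueError):
            rg.EffectSpec("XX9", "delta", 0.1)
        with pytest.raises(ValueError):
            rg.EffectSpec("O1", "sigma", 0.1)

    def test_baseline_unmodulated_by_effects(self):
        base = rg.SimulationConfig(seed=7, n_participants=1,
                                   tasks_per_participant=1,
                                   frames_per_task=60,
                                   baseline_duration=2.0,
                                   intercept_sd=0.0, montage=("O1",))
        with_eff = rg.SimulationConfig(
            seed=7, n_participants=1, tasks_per_participant=1,
            frames_per_task=60, baseline_duration=2.0, intercept_sd=0.0,
            montage=("O1",),
            effect_specs=(rg.EffectSpec("O1", "alpha", 0.5),))
        a = rg.generate_cohort(base).participants[0].recording
        b = rg.generate_cohort(with_eff).participants[0].recording
        sl = a.segment_slice("baseline")
        assert np.array_equal(a.data[:, sl], b.data[:, sl])


class TestCohort:
    def test_20x3_yields_60_task_recordings(self):
        cfg = rg.SimulationConfig(n_participants=20, tasks_per_participant=3,
                                  frames_per_task=30, baseline_duration=2.0,
                                  montage=("O1",), seed=0)
        bundle = rg.generate_cohort(cfg)
        assert bundle.n_task_recordings == 60
        assert len(bundle.participants) == 20

    def test_intercepts_drawn_per_cell(self, small_cohort):
        p = small_cohort.participants[0]
        assert len(p.intercepts) == 19 * 5
        sds = np.array(list(p.intercepts.values()))
        assert np.all(np.isfinite(sds))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            rg.SimulationConfig(n_participants=0)
        with pytest.raises(ValueError):
            rg.SimulationConfig(target_error_rate=1.0)
        with pytest.raises(ValueError):
            rg.SimulationConfig(intercept_sd=1.5)

    def test_write_cohort_deterministic_bytes(self, tmp_path):
        cfg = rg.SimulationConfig(seed=11, n_participants=1,
                                  tasks_per_participant=1, frames_per_task=30,
                                  baseline_duration=2.0, montage=("O1", "O2"))
        bundle = rg.generate_cohort(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        rg.write_cohort(bundle, d1)
        rg.write_cohort(rg.generate_cohort(cfg), d2)
        for rel in ("p00/eeg.csv", "p00/frames_task_1.csv"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()


class TestCalibration:
    def test_calibration_slopes_positive_and_below_unity(self):
        cal = _band_calibration(500.0, 30.0, 30.0)
        for band, (cv, sg, sp) in cal.items():
            assert 0.1 < cv < 1.5
            assert 0.3 < sp <= sg <= 1.05

    def test_effect_gain_monotone_in_effect_size(self):
        gains = [rg.synthetic.effect_gain(e, "alpha", 2, 0.3)
                 for e in (-0.1, -0.05, 0.0, 0.05, 0.1)]
        assert all(a < b for a, b in zip(gains, gains[1:]))
        assert gains[2] == pytest.approx(1.0)
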