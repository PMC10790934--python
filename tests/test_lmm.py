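"""Mixed-model fitting, batteries, correction, likelihood ratios.

The in-package profiled-ML fitter is cross-checked against statsmodels
MixedLM (ML) as an independent reference implementation.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import raseeg as rg
from raseeg.lmm import (CorrectionSpec, GroupStats, bonferroni, fit_lmm,
                        fit_lmm_from_stats, fit_null_lmm, likelihood_ratio,
                        results_table, run_channel_band_battery,
                        run_feature_battery, standardize, estimate_heatmap)


def _simulate(rng, n_groups=6, n_per=400, beta=0.1, isd=0.3, rate=0.3):
    g = np.repeat(np.arange(n_groups), n_per)
    x = (rng.random(n_groups * n_per) < rate).astype(float)
    y = beta * x + rng.normal(0, isd, n_groups)[g] + \
        rng.normal(0, 1.0, n_groups * n_per)
    return y, x, g


class TestStandardize:
    def test_two_point_example(self):
        assert standardize([1.0, 3.0]).tolist() == [-1.0, 1.0]

    def test_idempotent(self, rng):
        x = standardize(rng.normal(3, 5, 200))
        assert np.allclose(standardize(x), x, atol=1e-12)

    def test_output_moments(self, rng):
        z = standardize(rng.normal(10, 2, 500))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestFitLMM:
    def test_matches_statsmodels_ml_on_fixtures(self):
        rng = np.random.default_rng(99)
        for trial in range(10):
            y, x, g = _simulate(rng, beta=rng.uniform(-0.3, 0.3))
            ys = standardize(y)
            mine = fit_lmm(ys, x, g)
            sm = smf.mixedlm("y ~ x", pd.DataFrame({"y": ys, "x": x, "g": g}),
                             groups="g").fit(reml=False)
            assert mine.estimate == pytest.approx(sm.params["x"], abs=1e-4)
            assert mine.std_error == pytest.approx(sm.bse["x"], abs=1e-4)
            assert mine.log_likelihood == pytest.approx(sm.llf, abs=1e-3)

    def test_parameter_recovery_calibrated(self):
        """Estimator is unbiased and its SE well calibrated: across seeds
        the deviation/SE behaves like a standard normal."""
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y, x, g = _simulate(rng, n_groups=10, n_per=2000, beta=0.10)
            r = fit_lmm(standardize(y), x, g)
            assert r.converged
            devs.append((r.estimate - 0.10) / r.std_error)
        devs = np.array(devs)
        assert abs(devs.mean()) < 3 / np.sqrt(len(devs))
        assert np.sum(np.abs(devs) <= 2.0) >= 17

    def test_single_error_class_rejected(self, rng):
        y = rng.normal(size=100)
        with pytest.raises(ValueError):
            fit_lmm(y, np.zeros(100), np.repeat([0, 1], 50))

    def test_single_participant_pins_variance_at_zero(self, rng):
        y, x, _ = _simulate(rng, n_groups=1, n_per=2000)
        r = fit_lmm(standardize(y), x, np.zeros(2000))
        assert r.converged
        assert r.intercept_variance == pytest.approx(0.0, abs=1e-8)

    def test_joint_shuffle_leaves_fit_unchanged(self, rng):
        y, x, g = _simulate(rng)
        ys = standardize(y)
        a = fit_lmm(ys, x, g)
        perm = rng.permutation(len(ys))
        b = fit_lmm(ys[perm], x[perm], g[perm])
        assert a.estimate == pytest.approx(b.estimate, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    def test_stats_path_equals_array_path(self, rng):
        y, x, g = _simulate(rng)
        ys = standardize(y)
        a = fit_lmm(ys, x, g)
        b = fit_lmm_from_stats(GroupStats.from_arrays(ys, x, g))
        assert a.estimate == b.estimate and a.log_likelihood == b.log_likelihood


class TestBatteries:
    def test_toy_two_channel_battery_count(self, rng):
        from _helpers import make_table
        table = make_table({}, n_rows=40, channels=("O1", "O2"),
                           participants=("p0", "p1"))
        for col in table.values.columns:
            table.values[col] = rng.uniform(0.5, 2.0, 40)
        table.meta["error"] = rng.random(40) < 0.4
        results = run_channel_band_battery(table)
        assert len(results) == 10
        assert {r.model_id for r in results} == \
            {f"{c}_{b}" for c in ("O1", "O2") for b in rg.BAND_NAMES}

    def test_battery_continues_past_failures(self, rng):
        from _helpers import make_table
        table = make_table({}, n_rows=40, channels=("O1", "O2"),
                           participants=("p0", "p1"))
        for col in table.values.columns:
            table.values[col] = rng.uniform(0.5, 2.0, 40)
        table.values["O1_delta"] = 1.0          # constant -> standardize fails
        table.meta["error"] = rng.random(40) < 0.4
        results = {r.model_id: r for r in run_channel_band_battery(table)}
        assert len(results) == 10
        assert not results["O1_delta"].converged
        assert results["O2_delta"].converged

    def test_feature_battery_one_model_per_column(self, small_table):
        from raseeg.features import compute_features
        feats = compute_features(small_table)
        results = run_feature_battery(feats)
        assert len(results) == 16
        assert all(r.converged for r in results)

    def test_heatmap_masks_non_significant(self, rng):
        res = [rg.LMMResult(0.5, 0.01, 50.0, 1e-20, 0.0, 0.0, 1.0, 10, 2,
                            True, model_id="O1_delta"),
               rg.LMMResult(0.1, 0.1, 1.0, 0.3, 0.0, 0.0, 1.0, 10, 2,
                            True, model_id="O2_delta")]
        mat = estimate_heatmap(res, ("O1", "O2"), rg.BAND_NAMES, 1e-4)
        assert mat.loc["O1", "delta"] == 0.5
        assert np.isnan(mat.loc["O2", "delta"])


class TestCorrection:
    @pytest.mark.parametrize("alpha, n, expected", [
        (0.01, 110, 0.01 / 110),
        (0.05, 1, 0.05),
        (0.01, 1110, 0.01 / 1110),
    ])
    def test_bonferroni_arithmetic(self, alpha, n, expected):
        assert bonferroni(alpha, n) == pytest.approx(expected, rel=1e-12)

    def test_spec_object_interface(self):
        spec = CorrectionSpec(0.01, 110)
        assert bonferroni(spec) == spec.corrected_alpha
        with pytest.raises(ValueError):
            CorrectionSpec(0.01, 0)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_and_p_one(self, rng):
        y, x, g = _simulate(rng)
        fit = fit_lmm(standardize(y), x, g)
        stat, p = likelihood_ratio(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_strong_effect_gives_large_statistic(self, rng):
        y, x, g = _simulate(rng, beta=0.5, n_per=1000)
        ys = standardize(y)
        full = fit_lmm(ys, x, g)
        reduced = fit_null_lmm(ys, g)
        stat, p = likelihood_ratio(full, reduced)
        assert stat > 10 and p < 1e-3

    def test_statistic_matches_reference_refits(self, rng):
        y, x, g = _simulate(rng, beta=0.2)
        ys = standardize(y)
        stat, _ = likelihood_ratio(fit_lmm(ys, x, g), fit_null_lmm(ys, g))
        df = pd.DataFrame({"y": ys, "x": x, "g": g})
        llf = smf.mixedlm("y ~ x", df, groups="g").fit(reml=False).llf
        llr = smf.mixedlm("y ~ 1", df, groups="g").fit(reml=False).llf
        assert stat == pytest.approx(2 * (llf - llr), abs=1e-3)

    def test_inverted_nesting_raises(self, rng):
        y, x, g = _simulate(rng, beta=0.5, n_per=1000)
        ys = standardize(y)
        full = fit_lmm(ys, x, g)
        reduced = fit_null_lmm(ys, g)
        with pytest.raises(ValueError):
            likelihood_ratio(reduced, full)

    def test_results_table_flags_significance(self, rng):
        y, x, g = _simulate(rng, beta=1.0, n_per=2000)
        r = fit_lmm(standardize(y), x, g, model_id="m")
        df = results_table([r], corrected_alpha=9e-5)
        assert bool(df.loc[0, "significant_at_corrected"])
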