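"""Fit the mixed-model batteries on a cohort with a known injected effect.

Generates four participants with a +0.20 standardized error effect on
occipital delta power, fits the 95 channel-band models and the 16 feature
models (error fixed effect, participant random intercept), applies the
Bonferroni correction, and prints the headline rows.
"""

import raseeg as rg
from raseeg.features import compute_features
from raseeg.lmm import (CorrectionSpec, results_table,
                        run_channel_band_battery, run_feature_battery)
from raseeg.pipeline import cohort_band_powers

config = rg.SimulationConfig(
    n_participants=4, tasks_per_participant=1, frames_per_task=1500,
    baseline_duration=30.0,
    effect_specs=(rg.EffectSpec("occipital", "delta", +0.20),),
    seed=9)
table = cohort_band_powers(rg.generate_cohort(config))
features = compute_features(table)

cb = run_channel_band_battery(table)
ft = run_feature_battery(features)
corrected = CorrectionSpec(0.01, len(cb) + len(ft)).corrected_alpha
print(f"fitted {len(cb)} channel-band + {len(ft)} feature models; "
      f"corrected alpha = {corrected:.3g}")

df = results_table(ft, corrected).set_index("model_id")
cols = ["estimate", "std_error", "p", "significant_at_corrected"]
print("\nfeature battery (selected rows):")
print(df.loc[["occipital_delta", "parietal_alpha", "global_beta"],
             cols].round(4))
print("\nThe injected occipital-delta effect should surface as a positive "
      "estimate of roughly 0.2; uninjected features stay within sampling "
      "noise of zero (a few hundredths at this cohort size, more for the "
      "slow bands whose ~33 ms windows are strongly autocorrelated).")
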