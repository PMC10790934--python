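"""Simulation-based power for the error effect at the study design.

Estimates the power to detect a +/-0.05 standardized error effect with 20
participants x 18,402 windows each, 17.1% error prevalence, at the
corrected significance level 0.00009, with exact binomial confidence
intervals.
"""

from raseeg.power import PowerConfig, simulate_power

for effect, label in ((+0.05, "occipital delta style"),
                      (-0.05, "alpha asymmetry style")):
    res = simulate_power(PowerConfig(effect_size=effect, seed=11))
    print(f"effect {effect:+.2f} ({label}): power "
          f"{res.power_estimate:.4f}, 95% CI "
          f"{100 * res.ci_low:.2f}-{100 * res.ci_high:.2f}% "
          f"({res.n_rejections}/{res.n_sims} rejections)")

print("\nWith ~368k windows an |effect| of 0.05 is detected essentially "
      "always even at alpha = 9e-5; a full-success run of 1000 replicates "
      "pins the Clopper-Pearson lower bound at 0.025^(1/1000) ~ 99.63%.")
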