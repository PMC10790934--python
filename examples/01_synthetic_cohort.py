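"""Generate a small synthetic cohort and inspect its ground truth.

Builds two participants with a resting baseline and one simulation task
each, with a +0.05 standardized error effect injected on occipital delta
power, and prints the realized error prevalence and run structure.
"""

import numpy as np

import raseeg as rg

config = rg.SimulationConfig(
    n_participants=2, tasks_per_participant=1, frames_per_task=2000,
    baseline_duration=60.0,
    effect_specs=(rg.EffectSpec("occipital", "delta", +0.05),),
    seed=1)
bundle = rg.generate_cohort(config)

for p in bundle.participants:
    sched = p.schedules["task_1"]
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, sched.labels, 0])))[::2]
    print(f"{p.participant_id}: {len(sched)} frames, "
          f"{sched.error_fraction:.1%} error frames, "
          f"mean error run {runs.mean():.1f} frames, "
          f"EEG {p.recording.duration:.0f} s x {p.recording.n_channels} ch")

print(f"\nper-channel ground-truth effects (standardized): "
      f"{ {k: round(float(v), 4) for k, v in bundle.effect_map.items()} }")
print("Error frames arrive in ~1 s runs at ~17% prevalence, mirroring the "
      "study's detected error structure; each O1/O2 delta cell carries "
      "0.05/sqrt(2) so the occipital-delta feature carries 0.05.")
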