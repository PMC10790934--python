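# Methods

This note documents the models, numerical choices, and limitations behind
`raseeg`, in the order the pipeline runs.

## Error detection from console video

The simulator's error indicator is a saturated red overlay with
high-contrast text. The detector computes, per frame: the fraction of
pixels passing an HSV colour mask (hue within ±0.05 of pure red,
saturation ≥ 0.5, value ≥ 0.35); a text-region score (fraction of
near-white pixels inside the red mask's bounding box); optionally the 2-D
spectral high-frequency energy ratio and Hough-transform circles on a
Canny edge map (task-scene geometry, useful for scene QC rather than the
error decision). The decision rule is a threshold on the colour-mask
fraction (default 0.01, boundary closed: a frame exactly at threshold is
labelled error). All thresholds live in `DetectorParams`; the defaults are
tuned to the reference overlay rendered by `raseeg.frames` and would need
re-tuning for real console footage, whose indicator appearance is
proprietary. The HSV planes are computed channel-wise in float32 with hue
evaluated only on gated pixels, which keeps full-resolution classification
near the video rate on one core.

Zero-denominator precision/recall (no positive predictions, or no positive
truth) is reported as NaN with a warning rather than silently as 0.

## EEG preprocessing

Order is fixed: DC removal → 0.01–50 Hz bandpass → ASR → five-band
decomposition, all on the entire stream (baseline through last task)
before any windowing, so no analysis window straddles a filter start.

* **Filters.** 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) for zero phase — phase distortion would misalign the
  ~33 ms windows. The 0.01 Hz drift-removal leg is the one exception: its
  impulse response is longer than any desk-scale recording and the
  forward–backward IIR pass is numerically unstable at 500 Hz (measured
  ~18% passband error), so that leg is applied spectrally with the squared
  4th-order Butterworth magnitude response — the exact zero-phase target
  of the time-domain cascade, without the transient.
* **ASR.** Euclidean-space artifact subspace reconstruction: the
  baseline-segment covariance defines per-direction "clean" scales; the
  stream is processed in half-overlapping 0.5 s Hann windows; window
  principal components whose SD exceeds `cutoff` (default 20) calibration
  SDs in that direction are dropped and the window is reconstructed
  through the calibration mixing matrix (square root of the calibration
  covariance). When all components are retained the reconstruction is the
  identity, so clean data passes through unchanged (verified: channel
  correlations ≥ 0.95, RMS change < 5%). Rank-deficient calibration
  (e.g. a flat channel) raises an error naming the channel. ASR is applied
  to the full stream, baseline included, using the baseline as
  calibration.
* **Bands.** δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–50 Hz; shared printed
  edges are resolved half-open ([low, high)) for assignment; the analogue
  filters overlap naturally at edges. The 50 Hz lowpass partially shapes
  the upper γ band; the synthetic calibration runs through the same chain,
  so this is accounted for.

## Windowing and normalization

Each frame's window starts at the EEG sample nearest its timestamp (exact
midpoints break to the earlier sample — deterministic and
causality-preserving) and ends at the next frame's start; the last window
runs to the segment end and is kept if at least half the nominal frame
period; windows under 8 samples are dropped and logged. At exactly
500 Hz / 30 fps the lengths are 16 or 17 samples in the pattern forced by
500/30, partitioning the stream with no gaps or overlaps. Segment
boundaries are half-open in time: a sample exactly on a boundary belongs
to the later segment.

Window power is the RMS of the band-filtered amplitude, computed from
cumulative sums of squares (equal to the direct definition to 1e-12).
Since no video exists during the resting baseline, the baseline is cut at
the nominal frame period (1/30 s), making baseline and task powers
unit-compatible; normalization is the ratio of window RMS to the
per-(channel, band) baseline mean (a log-ratio option exists). The
windowed baseline mean sits slightly below the process RMS (Jensen's
inequality; ~20% for δ whose correlation time exceeds the window, ~3% for
γ) — this cancels in the ratio across conditions and is absorbed by
standardization.

## Features

The 16 registered features are regional means, band ratios, and the
left/right α asymmetry over the 10–20 montage. Ratios aggregate each side
per band as the channel mean and sum across bands before dividing, so the
β:(α+θ) ratio of a uniform table of value p is p/(p+p) = 1/2. The
asymmetry is the ratio of left-set to right-set α means ("left-to-right"),
with a log-ratio option. Features are computed from baseline-normalized
channel powers (normalize-then-aggregate). The published feature count is
15 but the published electrode-set table de-duplicates to 16 distinct
definitions; all 16 are implemented, and a `paper15` preset drops an
explicit one. No construct-validity claim is made for any feature.

## Mixed-effects battery

Per outcome (channel-band cell or feature): the outcome is z-scored over
all included windows pooled across participants (population SD, so
[1, 3] → [−1, 1]; pooled rather than within-participant scaling because
the random intercept absorbs participant offsets and per-participant
scaling would change the estimand), then fitted with
y = β₀ + β₁·error + u_participant + ε by **maximum likelihood** — not
REML — because the validation compares models differing in fixed effects
via likelihood ratios, which is only valid under ML. β₁ is tested with a
Wald z, appropriate at 10⁴–10⁵ windows.

The fitter is closed-form: per-participant sufficient statistics (n, Σx,
Σx², Σy, Σy², Σxy) reduce the likelihood to a 1-D profile over the
variance ratio σ²ᵤ/σ²ₑ, optimized by bounded scalar search with the θ = 0
boundary checked explicitly. A single-participant fit pins the random
intercept variance at 0 (it is confounded with the intercept).
Consequences: fit cost is independent of window count once statistics are
accumulated, and the estimator is invariant under any joint row
permutation up to float summation order (~1e-14) — the shuffle-robustness
check holds by construction since the model ignores temporal ordering.
The fitter agrees with statsmodels `MixedLM(reml=False)` to ≤1e-4 on
estimate, SE, and log-likelihood on fixture data (tested).

Residual autocorrelation between consecutive 33 ms windows is deliberately
not modelled, matching standard practice for this model family; it
inflates the true sampling variability of estimates relative to the model
SE (strongly for δ, whose band correlation time spans ~10 windows,
mildly for β/γ). Tests that assert ±2·SE recovery therefore use the
reduced-form simulation with independent residuals; full-pipeline tests
use paired-noise, sign, or CI-overlap designs instead.

Multiple comparisons: Bonferroni from baseline α = 0.01 over the number of
models actually fitted (95 + 16 = 111 by default; 110 with the `paper15`
preset, giving 0.01/110 ≈ 9.1e-5, i.e. 0.00009 at one significant
figure). The originally printed correction factor of 1110 is inconsistent
with both the printed corrected level and the 110-model family and is not
the default.

## Power analysis

Each replicate draws the standardized outcome from the fitted family —
intercepts N(0, intercept_sd²) with default 0.3 (not printed anywhere;
chosen so total variance is 1 with residual SD √0.91, and exposed as a
knob because power at small effects is sensitive to it), Bernoulli error
labels at 17.1%, effect·error added — fits the same ML model, and records
two-sided rejection at α = 9e-5. 1000 replicates are used (a full-success
run then has Clopper–Pearson lower bound 0.025^(1/1000) ≈ 0.9963, matching
the reported 99.6% lower bounds, which implies ≈1000 replicates). For
speed the default path draws the per-participant, per-class sufficient
statistics directly: class sums from their normal law and sums of squares
as (sum)²/n plus an independent σ²ₑ·χ²ₙ₋₁ remainder — distributionally
identical to drawing every window (cross-checked against explicit
per-window simulation), making the 368k-window design run in seconds.
Replicates with a single error class are redrawn (impossible in practice
at this design). A likelihood-ratio-test variant (`statistic="lr"`) is
provided; power CIs reported for |effect| ≈ 0.02–0.03 depend on the
unprinted variance components and are not reproduced.

## Synthetic cohort generator

The generator's defaults are the study conditions: 20 participants ×
3 tasks × 6,134 frames (equal split of the 368,043 total; per-participant
counts were never published), 30 fps, 500 Hz, 240 s baseline, 17.1% error
prevalence in geometric runs of mean 30 frames (~1 s; memoryless runs are
the simplest stationary process with controllable prevalence and
realistic multi-frame errors), intercept SD 0.3.

EEG is a sum over bands of band-filtered white noise with amplitudes
∝ 1/(band centre frequency) — a 1/f-like spectrum with controllable
per-band power. Effects and participant intercepts are multiplicative
amplitude gains on individual band components, applied only during task
segments (baseline never modulated).

**Calibration.** Requested effects are on the standardized
baseline-normalized power scale, so the generator measures, once per band
through the real downstream chain on a 240 s pilot stretch (fixed internal
seed; a design constant, not user randomness):

* `cv` — coefficient of variation of window RMS, which sets the
  standardized scale: the pooled SD of normalized power is
  σₓ = cv/√(1 − intercept_sd²);
* `slope_global` — response of mean RMS to a sustained component gain
  (slightly < 1 from neighbour-band leakage), used for intercepts;
* `slope_pulse` — response of the error/non-error window separation to a
  gain applied only inside error-run pulses, measured with gained and
  ungained streams sharing one noise realization so sampling noise
  cancels. The band filter smears pulse edges over its impulse response,
  so this is the slope that governs injected error effects.

The gain for effect e on a k-channel region is then
g = 1 + e·σₓ/(slope_pulse·√k): a multi-channel `EffectSpec` targets the
*regional-mean feature* (averaging k independent channels shrinks the
feature SD by √k), and each member channel individually carries e/√k.
Paired on/off cohorts recover injected effects to within ~±0.01 at desk
scale; single-run estimates scatter more in the slow bands for the
autocorrelation reasons above.

**What the generator does not emulate:** volume conduction and
inter-channel correlation, non-Gaussian artifacts outside the explicit
burst fixtures, eye/muscle activity, skill-level differences, non-red
error indicators, and temporal nonstationarity beyond the error gains.
Passing tests demonstrate the pipeline's correctness and statistical
calibration on data obeying its assumptions, not clinical validity on
real recordings.

## Scales used by the test suite

Simulations are sized for a single CPU: cohort tests use 4–8 participants
× 1,200–1,800 frames with 30 s baselines; the detector validation uses
10,000 rendered frames at 640×360; the null-calibration and recovery
checks use 10 participants × 1,000–5,000 reduced-form windows over
1,000/20 seeds; the headline power simulations run the full 20 × 18,402
design (cheap via sufficient statistics). The acceptance script reruns
the two power targets at full design scale with 1000 replicates.
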