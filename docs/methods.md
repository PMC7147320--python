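# Methods

This note records the model underlying `rowemg`, the parameters that
matter, the design choices made where the method description left the
design open, and the known limitations of validating the pipeline on
synthetic data.

## Signal model

A rowing trial is modelled as 16 bipolar sEMG channels (8 leg muscles ×
left/right) sampled at `fs` = 2048 Hz in µV, plus a handle-position
trace in mm on the same timeline. Surface EMG during cyclic exercise is
treated as amplitude-modulated, band-limited Gaussian noise: the
physiological information is in the modulation envelope, not the
carrier. A ≥ 5 s rest recording per channel captures the noise floor
(electrode/amplifier noise plus residual muscle tone).

## Envelope extraction

`envelope(x) = LP₅(|BP₂₀₋₄₀₀(x)|)`, both filters 2nd-order Butterworth
applied forward and backward (zero phase). Corners are the −3 dB points
of a single pass, so the combined two-pass response is −6 dB at 20, 400
and 5 Hz. Zero phase matters because all downstream timing is read off
the envelope; a causal filter would delay every onset by the group
delay. Implementation details:

* Explicit even-reflection padding of 3× the filter's characteristic
  length (`3·fs/f_corner` samples) before each pass suppresses endpoint
  transients that would corrupt the first and last cycles.
* Zero-phase low-passing a rectified signal can ring below zero;
  negative envelope samples are clamped to 0 so threshold crossings are
  well defined.
* For amplitude-modulated Gaussian noise with slowly varying scale
  σ(t), the envelope estimates `E|N(0, σ²)| = √(2/π)·σ(t)` ≈ 0.80·σ(t),
  with relative point-wise fluctuation ≈ 8% (set by the ratio of the
  5 Hz smoother bandwidth to the 20–400 Hz signal bandwidth, not by the
  noise level).

## Cycle segmentation and normalisation

Catches (handle minima) and finishes (maxima) are detected on a 5 Hz
zero-phase low-passed copy of the handle trace (`scipy.signal
.find_peaks`, prominence ≥ 100 mm — the handle excursion is ~1 m, ripple
is mm-scale — and spacing ≥ half the nominal cycle), then each extremum
is refined on the raw trace within ±0.1 s to remove smoothing bias.
Cycle *k* spans catch *k* → catch *k+1* (0–100%); the finish falls
inside the cycle. Incomplete first/last cycles are discarded. Signals
are linearly interpolated to N = 100 points per cycle.

The catch-anchored convention with *negative* percentages for instants
in the preceding recovery avoids circular-mean wraparound when
averaging onsets of muscles recruited just before the catch; a
silencing that outlasts the cycle (rectus femoris) is reported above
100%.

## Activity detection

**Threshold.** The baseline margin is `b = k·SD(e_rest)` with k = 5.
The detection threshold applied to trial envelopes is
`θ = mean(e_rest) + b` by default. The mean term is not optional in
practice: the envelope of rest-level noise fluctuates around
0.80·σ_rest with SD ≈ 0.06·σ_rest, so a threshold of 5·SD ≈ 0.32·σ_rest
lies *below* the level the envelope never leaves — it would classify
every instant as active and no silencing could ever be detected.
`TimingParams(include_rest_mean=False)` restores the bare-margin
variant for comparison.

**Crossings.** Supra-threshold runs are located over the whole record;
run boundaries are linearly interpolated between the bracketing
envelope samples (exact for locally linear envelopes). Exact-equality
plateaus take the earliest sample for activation and the latest for
silencing. Each run is attributed to the cycle containing its midpoint;
per cycle, onset = start of the first run, silencing = end of the last,
and duration = algebraic sum of the run lengths in % of cycle. Cycles
whose envelope never crosses the threshold are flagged `silent`; cycles
fully covered by one run are flagged `always_on`. Both are excluded
from averages but counted in the quality report. No minimum-duration
debounce is applied by default (`debounce_pct = 0`).

Midpoint attribution (rather than a fixed search window anchored at the
finish) handles every case uniformly: pre-catch onsets, post-catch
silencings, multiple bursts per cycle, and recovery-phase muscles.

**Intrinsic bias.** The threshold sits at ≈ 2% of a 20×-noise burst's
envelope amplitude, i.e. in the foot of the burst edge, where the 5 Hz
smoother leaks outward by ~25 ms. Detected onsets are therefore ~1% of
cycle early and silencings ~1% late at 24 spm, and durations ~2% of
cycle wide, independent of the activity span. This is a property of the
envelope-threshold method itself, not of the implementation; real
recordings analysed this way carry the same widening.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes:

* **Handle**: raised-cosine drive (catch → finish over `drive_fraction`
  = 0.4 of the cycle) and slower raised-cosine recovery; one clean
  minimum and maximum per cycle; half-recovery lead-in and half-drive
  lead-out so all `n_cycles`+1 catches are interior extrema.
* **EMG**: unit-SD noise band-limited to 20–400 Hz, multiplied by
  `σ(t) = g_side·(σ_rest + peak·w(t))` with `w` the burst profile. The
  multiplicative construction (not an added deterministic waveform)
  gives the rectified envelope realistic variance. The side gain is an
  electrode-level gain: it scales burst and noise floor alike, and the
  rest recording with it.
* **Burst profile**: trapezoid with rise/fall ramps of 5% of the cycle
  (~0.1 s at the protocol rates, comparable to the 5 Hz smoother's
  resolution). Edges much sharper than the smoother cannot be resolved
  and inflate the outward crossing bias; much smoother edges (the
  `hann` option) leave the nominal onset operationally undefined at
  threshold level. The trapezoid makes the generator's ground-truth
  timing recoverable to ~1% of cycle.
* **Jitter**: cycle durations jitter with SD `jitter_pct` = 5% of
  nominal (matching the few-percent spread of real cycle durations),
  and burst timing scales proportionally, so cycle-relative timing is
  invariant under duration jitter. An additive per-cycle timing jitter
  (`timing_jitter_pct` = 3% of cycle) models neuromuscular
  cycle-to-cycle variability and reproduces onset SDs in the
  few-percent range observed in practice. Timing jitter is shared by
  the two sides of a muscle by default (bilateral common drive), which
  is what "symmetric timing" means physiologically; side-independent
  jitter is available.
* Default per-muscle timing follows the qualitative picture in elite
  rowing (quadriceps/triceps surae on just before the catch, rectus
  femoris active longest at 51% of the cycle, biceps femoris briefest
  at 22%, tibialis anterior alone in recovery). Default amplitudes
  (peak 100 µV over a 3 µV rest floor) are free parameters chosen to
  give realistic envelope SNR.

Determinism: identical `SessionSpec` (including seed) produces
bit-identical output; every channel draws from an independent,
label-stable stream.

## Bilateral symmetry

Left and right envelopes of a muscle are paired over the per-cycle
*union* of the two sides' detected active windows (the method
description does not fix how unequal windows are aligned; the union is
the choice that discards no activity), resampled to N = 100, averaged
across cycles, and each side normalised to the peak of its own mean
curve. Normalising instead by the maximum over *individual* cycles
(`mode="cycle_max"`) is supported but not default: that maximum is an
extreme-value statistic with ~3% sampling noise, independent between
legs, which masquerades as amplitude asymmetry.

`bilateral_stats` reports Pearson R and the OLS slope of left on right
with the textbook t-test against slope 1. For the pipeline results the
slope-vs-unity p-value is computed instead by a delete-one-cycle
jackknife: the 100 curve points are 5 Hz-smoothed and therefore
strongly autocorrelated (~10 effective degrees of freedom), making the
naive t-test anti-conservative by a factor ~3 (measured type-I error
~40% under a symmetric generator; HAC corrections still ~20%). Cycles
are genuine independent replicates, and the jackknife test is
calibrated (measured size ≤ 5%).

## Group statistics

Timing outcomes form a balanced subject × stroke-rate × muscle × side
table. Because every subject performs all rates with all muscles on
both sides, all three factors are within-subject; the ANOVA is
`statsmodels` AnovaRM with subject as the random unit (replicates
averaged per cell). Shapiro–Wilk (per group) and Levene (mean-centred)
gate the parametric analysis. Pairwise muscle comparisons are paired
t-tests across subjects with Bonferroni correction (p × 28, capped at
1). Pooling across stroke rates happens only after a non-significant
rate main effect, and the decision is logged.

For single-trial analyses (one session per rate) the rowing cycle
stands in as the repeated unit for a muscle × side ANOVA per rate;
statistical calibration experiments simulate the timing table directly
(muscle mean + subject effect + within-cell noise) rather than running
hundreds of full EMG pipelines.

## Problem sizes

Validation uses 30-cycle trials at 18/24/28 spm and 2048 Hz (the
protocol's trial length), 100-seed replications for symmetry
statistics, and 100–200 simulated timing tables for ANOVA calibration —
sizes at which every Monte-Carlo bound in the test suite is stable
while the whole suite runs in a few minutes on one CPU.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the pipeline
assumes: band-limited noise with burst-modulated amplitude, a unimodal
handle trace, proportional plus additive timing jitter, gain
asymmetries. It does not emulate motor-unit physiology, force or
kinematics, movement artefacts, electrode lift-off, crosstalk between
muscles, or within-burst amplitude substructure (double peaks during
the drive, effort drift across a trial). Parameter recovery on this
generator therefore validates the *estimator* — segmentation, threshold
logic, interpolation, normalisation, test calibration — not the
biological interpretability of any specific real recording. Channels
with real-data pathologies are expected to be caught by
`validate_recording` and the exclusion list, which replace manual
visual inspection for reproducibility.

## Known limitations

* The duration estimate carries the +2%-of-cycle smoothing widening
  discussed above; comparisons *between* muscles or conditions are
  unaffected (the bias is common mode), absolute durations are.
* The first complete cycle has no preceding finish; runs are attributed
  by midpoint so it is analysed, but a burst beginning before the
  recording starts is truncated at the record edge.
* With `include_rest_mean=False` the detector matches the bare
  "5 × SD" definition but classifies rest-level noise as activity
  whenever the rest envelope's mean exceeds the margin — i.e. always,
  for Gaussian noise. The default therefore includes the mean.
* `AnovaRM` assumes sphericity; no Greenhouse–Geisser correction is
  applied (a logged Mauchly check is out of scope).
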