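# rowemg

**When, and how symmetrically, are leg muscles active during indoor rowing?**

`rowemg` is a Python library for turning multichannel surface
electromyography (sEMG) recorded during ergometer rowing — together with
the synchronously sampled handle-position trace — into cycle-relative
muscle activation timing and bilateral symmetry statistics. It is aimed
at movement scientists and engineers designing functional electrical
stimulation (FES) rowing protocols, where knowing *which* leg muscles to
stimulate and *when in the stroke* is the central design question.

The package also ships a synthetic session generator with known
ground-truth timing, so every stage of the pipeline is validated by
parameter recovery rather than by eye.

## The method

For each EMG channel (8 muscles × 2 body sides, sampled at 2048 Hz):

1. **Envelope** — zero-phase band-pass 20–400 Hz (2nd-order Butterworth
   per pass, −6 dB at the corners over the two passes), full-wave
   rectification, zero-phase 5 Hz low-pass:
   `e(t) = LP₅(|BP₂₀₋₄₀₀(x)(t)|)`.
2. **Cycles** — catches and finishes are the minima and maxima of the
   handle position; cycle *k* spans catch *k* → catch *k+1* and maps
   onto 0–100% of the cycle. Signals are resampled to N = 100 points
   per cycle.
3. **Timing** — a rest recording defines the baseline margin
   `b = 5·SD(e_rest)`; the detection threshold is the rest-envelope mean
   plus that margin. Activation onset and silencing are the first and
   last threshold crossings of each cycle's activity, located by linear
   interpolation between the bracketing envelope samples and expressed
   in % of cycle (negative = before the catch). The duration of
   activity is the algebraic sum of the supra-threshold intervals.
4. **Symmetry** — per muscle, the envelope between recruitment and
   silencing is averaged across cycles, resampled to N = 100 points and
   normalised per leg; left is regressed on right. Pearson *R* measures
   synchrony of modulation, and a slope indistinguishable from 1 (cycle
   -jackknife test) means both legs modulate by equal relative amounts.
5. **Group statistics** — Shapiro–Wilk and Levene gates, then a
   repeated-measures ANOVA of timing outcomes over stroke rate (18, 24,
   28 spm) × muscle × side with subject as the random unit, Bonferroni
   -corrected pairwise comparisons, and automatic pooling across stroke
   rates when the rate effect is absent.

## A worked example

```python
from rowemg.synth import SessionSpec, BurstSpec, gen_session
from rowemg.pipeline import analyze_recording

spec = SessionSpec(
    spm=24, n_cycles=30,
    bursts={("vastus_lateralis", s): BurstSpec(-5.0, 36.0, peak_uv=100.0)
            for s in ("left", "right")},
    seed=7,
)
rec, rest, truth = gen_session(spec)     # EMG + handle + rest recording
res = analyze_recording(rec, rest)       # envelopes -> cycles -> timing
```

Running `python examples/01_timing_recovery.py` (which adds a
recovery-phase muscle) prints:

```
cycles detected: 30 (generated: 30)

channel                         true on/off    detected on/off  duration %
vastus_lateralis_left          -5.0/ 36.0     -5.9/ 37.3      43.2
vastus_lateralis_right         -5.0/ 36.0     -5.9/ 37.3      43.2
tibialis_anterior_left         55.0/ 90.0     54.4/ 91.5      37.1
tibialis_anterior_right        55.0/ 90.0     54.4/ 91.6      37.2
```

Detected onsets/silencings land within ~1% of cycle of the generated
truth; the ~2%-of-cycle widening of duration is the intrinsic smoothing
bias of the 5 Hz envelope (see `docs/methods.md`). The symmetry example
(`examples/02_bilateral_symmetry.py`) shows that a two-fold
electrode-gain difference between legs leaves R = 0.997 and slope =
1.02 ± 0.02 (p = 0.20 vs unity): amplitude asymmetries of
non-physiological origin are fully absorbed by the per-leg
normalisation.

Other examples: `03_group_statistics.py` (gates + repeated-measures
ANOVA + post-hocs on a 20-subject timing table) and
`04_session_io_and_cli.py` (plain-text session containers).

## Command-line interface

```bash
rowemg synth   --out trial24 --seed 3          # synthetic session + ground truth
rowemg analyze --config pipeline.yaml          # full configured pipeline
rowemg demo    --out demo_out --seed 1         # end-to-end run with recovery scoring
```

`analyze` reads every parameter from a single YAML config and writes
`timing_cycles.csv`, `timing_summary.csv`, `symmetry.csv`, `stats.json`
and a `run_log.json` recording all numeric parameters and exclusions.
Exit codes: 0 success, 2 configuration error, 3 data error.

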