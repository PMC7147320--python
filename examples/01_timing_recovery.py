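"""Detect muscle on/off timing in a synthetic rowing trial.

Generates one trial (30 strokes at 24 spm) with two bilateral muscles
whose true activation windows are known, runs the full envelope ->
cycle-segmentation -> threshold-detection pipeline, and compares the
detected cycle-relative timing with the generator's ground truth.
"""

from rowemg.pipeline import analyze_recording
from rowemg.synth import BurstSpec, SessionSpec, gen_session

spec = SessionSpec(
    spm=24,
    n_cycles=30,
    bursts={
        # vasti: recruited just before the catch, silenced before finish
        ("vastus_lateralis", "left"): BurstSpec(-5.0, 36.0, peak_uv=100.0),
        ("vastus_lateralis", "right"): BurstSpec(-5.0, 36.0, peak_uv=100.0),
        # tibialis anterior: the recovery-phase muscle
        ("tibialis_anterior", "left"): BurstSpec(55.0, 90.0, peak_uv=80.0),
        ("tibialis_anterior", "right"): BurstSpec(55.0, 90.0, peak_uv=80.0),
    },
    seed=7,
)
rec, rest, truth = gen_session(spec)
res = analyze_recording(rec, rest)

print(f"cycles detected: {res.cycle_set.n_cycles} (generated: {truth.n_cycles})")
print()
print(f"{'channel':28s} {'true on/off':>14s} {'detected on/off':>18s} {'duration %':>11s}")
ok = res.rows[res.rows.flag == "ok"]
for (m, s), burst in spec.bursts.items():
    g = ok[(ok.muscle == m) & (ok.side == s)]
    print(
        f"{m + '_' + s:28s} {burst.onset_pct:6.1f}/{burst.offset_pct:5.1f} "
        f"{g.onset_pct.mean():8.1f}/{g.silencing_pct.mean():5.1f} "
        f"{g.duration_pct.mean():9.1f}"
    )

# Timing is expressed in % of the rowing cycle (catch = 0%, next catch =
# 100%); negative onsets mean the muscle turns on during the preceding
# recovery.  Detected onsets sit within ~1% of the true values; the
# detected duration is ~2% wider than the generated span, the intrinsic
# widening introduced by the 5 Hz envelope smoothing.
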