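"""Group-level statistics over muscle-timing outcomes.

Simulates a balanced timing table for 20 subjects x 3 stroke rates x
8 muscles x 2 sides (onsets in % of cycle), checks the distributional
gates, runs the repeated-measures ANOVA with subject as the random unit,
pools across stroke rates when the rate effect is absent, and applies
Bonferroni-corrected pairwise muscle comparisons.
"""

from rowemg.group_stats import (
    anova_timing,
    bonferroni_pairwise,
    check_then_pool,
    normality_gate,
    variance_gate,
)
from rowemg.synth import simulate_timing_table

tbl = simulate_timing_table(n_subjects=20, noise_sd=3.0, seed=5)
print(f"timing table: {len(tbl)} rows "
      f"({tbl.subject.nunique()} subjects x 3 rates x 8 muscles x 2 sides)")

groups = {m: g.onset_pct.to_numpy() for m, g in tbl.groupby("muscle")}
ng = normality_gate(groups)
W, p_lev = variance_gate(groups)
print(f"normality gate:  min Shapiro-Wilk p = {min(ng.p_values.values()):.3f} "
      f"({'pass' if ng.passed else 'FAIL'})")
print(f"variance gate:   Levene W = {W:.2f}, p = {p_lev:.3f}")

effects = anova_timing(tbl, "onset_pct")
print("\nrepeated-measures ANOVA on onset (% of cycle):")
for _, r in effects.iterrows():
    print(f"  {r.effect:28s} F = {r.F:8.2f}   p = {r.p:.4g}")

pooled, log = check_then_pool(tbl, "onset_pct")
print(f"\nstroke-rate effect p = {log['stroke_rate_p']:.3f} -> "
      f"{'pooled across rates' if log['pooled_across_rates'] else 'kept per rate'}")

post = bonferroni_pairwise(tbl, "onset_pct")
sig = post[post.p_adj < 0.05]
print(f"Bonferroni post-hoc: {len(sig)}/{len(post)} muscle pairs differ (p_adj < 0.05)")

# The muscle main effect dominates (muscles genuinely start at different
# cycle phases), the side effect is null by construction, and onsets are
# pooled across rates exactly as one would for real trials in which
# stroke rate does not shift the cycle-relative timing.
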