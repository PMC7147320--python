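"""Distributional gates and the repeated-measures ANOVA over timing outcomes.

Timing outcomes (activation onset, silencing, duration, all in % of
cycle) are arranged as a balanced table of subject x stroke rate x
muscle x body side.  Normality (Shapiro-Wilk) and homogeneity of
variance (Levene, mean-centred) gate the parametric analysis; the main
analysis is a three-factor repeated-measures ANOVA with subject as the
random unit — every subject rows at all three rates with all muscles on
both sides, so all three factors are within-subject.  Significant main
effects are followed by Bonferroni-corrected pairwise comparisons.

Onsets are pooled across stroke rates only after a non-significant
stroke-rate main effect (check-then-pool), and the decision is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.anova import AnovaRM

from .signal_model import SessionError

FACTORS = ["stroke_rate", "muscle", "side"]


@dataclass
class GateResult:
    p_values: dict = field(default_factory=dict)
    passed: bool = True
    skipped: list = field(default_factory=list)  # groups with n < 3
    degenerate: list = field(default_factory=list)  # constant-valued groups


def normality_gate(groups: dict, alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk per group; the gate passes when every p > alpha.

    Groups with fewer than 3 values are skipped with a warning entry;
    constant groups are flagged degenerate and not tested.
    """
    res = GateResult()
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=np.float64)
        if vals.size < 3:
            res.skipped.append(name)
            continue
        if np.ptp(vals) == 0:
            res.degenerate.append(name)
            continue
        _, p = sst.shapiro(vals)
        res.p_values[name] = float(p)
        if p <= alpha:
            res.passed = False
    return res


def variance_gate(groups: dict) -> tuple[float, float]:
    """Levene's test (mean-centred) across groups; returns (W, p)."""
    arrays = [np.asarray(v, dtype=np.float64) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise SessionError("Levene needs >= 2 groups with n >= 2 each")
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0
    W, p = sst.levene(*arrays, center="mean")
    return float(W), float(p)


def _check_balanced(tbl: pd.DataFrame, outcome: str) -> None:
    for col in ["subject", *FACTORS, outcome]:
        if col not in tbl.columns:
            raise SessionError(f"timing table missing column {col!r}")
    cell = tbl.groupby(["subject", "stroke_rate", "muscle"])["side"].nunique()
    if (cell < 2).any():
        bad = cell[cell < 2].index.tolist()[:5]
        raise SessionError(
            "unbalanced side factor (both sides required per subject cell); "
            f"exclude incomplete cells rather than imputing: {bad}"
        )


def anova_timing(tbl: pd.DataFrame, outcome: str = "onset_pct") -> pd.DataFrame:
    """Repeated-measures ANOVA of a timing outcome.

    Returns an effects table (effect, F, df_num, df_den, p) for the three
    main effects and all interactions.  Replicate observations within a
    subject cell are averaged first.  A constant outcome is returned
    with all F = 0 and flagged degenerate.
    """
    _check_balanced(tbl, outcome)
    if np.ptp(tbl[outcome].to_numpy()) == 0:
        effects = FACTORS + [
            ":".join(c) for r in (2, 3) for c in combinations(FACTORS, r)
        ]
        return pd.DataFrame(
            {"effect": effects, "F": 0.0, "df_num": np.nan, "df_den": np.nan,
             "p": 1.0, "degenerate": True}
        )
    res = AnovaRM(
        tbl, depvar=outcome, subject="subject", within=FACTORS, aggregate_func="mean"
    ).fit()
    at = res.anova_table
    return pd.DataFrame(
        {
            "effect": at.index,
            "F": at["F Value"].to_numpy(),
            "df_num": at["Num DF"].to_numpy(),
            "df_den": at["Den DF"].to_numpy(),
            "p": at["Pr > F"].to_numpy(),
            "degenerate": False,
        }
    ).reset_index(drop=True)


def anova_muscle_side(
    tbl: pd.DataFrame, outcome: str = "onset_pct", subject_col: str = "subject"
) -> pd.DataFrame:
    """Two-factor (muscle x side) repeated-measures ANOVA.

    Used when only one stroke rate is present (e.g. a single trial
    analysed with the rowing cycle as the repeated unit).
    """
    within = [f for f in ("muscle", "side") if tbl[f].nunique() > 1]
    if np.ptp(tbl[outcome].to_numpy()) == 0 or not within:
        return pd.DataFrame(
            {"effect": ["muscle", "side", "muscle:side"], "F": 0.0,
             "df_num": np.nan, "df_den": np.nan, "p": 1.0, "degenerate": True}
        )
    res = AnovaRM(
        tbl, depvar=outcome, subject=subject_col, within=within,
        aggregate_func="mean",
    ).fit()
    at = res.anova_table
    return pd.DataFrame(
        {
            "effect": at.index,
            "F": at["F Value"].to_numpy(),
            "df_num": at["Num DF"].to_numpy(),
            "df_den": at["Den DF"].to_numpy(),
            "p": at["Pr > F"].to_numpy(),
            "degenerate": False,
        }
    ).reset_index(drop=True)


def bonferroni_pairwise(
    tbl: pd.DataFrame, outcome: str = "onset_pct", factor: str = "muscle"
) -> pd.DataFrame:
    """All-pairs paired t-tests across subjects with Bonferroni correction.

    Values are first averaged within subject x level (collapsing the
    remaining factors); each pair of levels is compared with a paired t
    across subjects and the raw p multiplied by the number of
    comparisons, capped at 1.  Identical groups yield adjusted p = 1.
    """
    means = tbl.groupby(["subject", factor])[outcome].mean().unstack(factor)
    levels = list(means.columns)
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = (means[a] - means[b]).dropna().to_numpy()
        if diff.size < 2 or np.allclose(diff, 0):
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = sst.ttest_rel(means[a].to_numpy(), means[b].to_numpy())
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_adj": min(1.0, m * float(p_raw)),
                "n_comparisons": m,
            }
        )
    return pd.DataFrame(rows)


def check_then_pool(
    tbl: pd.DataFrame, outcome: str = "onset_pct", alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Average across stroke rates only if the rate main effect is non-significant.

    Returns the (possibly pooled) table and a log dict recording the
    decision and the stroke-rate effect p-value.
    """
    effects = anova_timing(tbl, outcome)
    p_rate = float(effects.loc[effects["effect"] == "stroke_rate", "p"].iloc[0])
    pooled = p_rate > alpha
    log = {"outcome": outcome, "stroke_rate_p": p_rate, "pooled_across_rates": pooled}
    if pooled:
        out = (
            tbl.groupby(["subject", "muscle", "side"], as_index=False)[outcome]
            .mean()
            .assign(stroke_rate="pooled")
        )
        return out, log
    return tbl, log
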