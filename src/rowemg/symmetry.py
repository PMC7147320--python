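"""Bilateral symmetry of muscle-activity modulation.

For each muscle the envelope between activation onset and silencing is
extracted per cycle, linearly resampled to N = 100 points, averaged
across cycles, and normalised by the maximal envelope value observed
across all of that leg's cycles (suppressing between-side amplitude
differences of non-physiological origin, e.g. electrode-skin impedance).
Synchrony of the left/right modulation is quantified by the Pearson
correlation of the two normalised mean curves; equality of modulation
depth by the ordinary-least-squares slope of left (ordinate) on right
(abscissa) tested against unity.

Left and right active windows need not coincide; the curves are paired
over the per-cycle *union* of the two sides' active windows so both
samples cover the same instants of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .cycles import CycleSet
from .signal_model import SessionError


@dataclass(frozen=True)
class SymmetryResult:
    muscle: str
    R: float
    R_p: float
    slope: float
    slope_se: float
    slope_p_vs_unity: float
    intercept: float
    n_points: int
    degenerate: bool = False  # zero-residual fit: t-statistic undefined


def _window_matrix(
    env: np.ndarray,
    cs: CycleSet,
    windows: dict[int, tuple[float, float]],
    N: int = 100,
) -> np.ndarray:
    """Resample the envelope over each cycle's (start_pct, end_pct) window."""
    bounds = cs.bounds.astype(float)
    t = np.arange(env.size)
    mat = []
    for k, (a_pct, b_pct) in sorted(windows.items()):
        c, nc = bounds[k], bounds[k + 1]
        dur = nc - c
        t0 = c + a_pct / 100.0 * dur
        t1 = c + b_pct / 100.0 * dur
        if t1 <= t0:
            continue
        grid = np.linspace(t0, t1, N)
        mat.append(np.interp(grid, t, env))
    if not mat:
        raise SessionError("no valid cycles with an active window")
    return np.asarray(mat)


def active_windows(rows: pd.DataFrame) -> dict[int, tuple[float, float]]:
    """Per-cycle (onset, silencing) windows from valid timing rows."""
    if rows.empty or "flag" not in rows.columns:
        return {}
    ok = rows[rows["flag"] == "ok"]
    return {
        int(r.cycle): (float(r.onset_pct), float(r.silencing_pct))
        for r in ok.itertuples()
    }


def union_windows(
    rows_left: pd.DataFrame, rows_right: pd.DataFrame
) -> dict[int, tuple[float, float]]:
    """Cycles valid on both sides, spanned by the union of active windows."""
    wl, wr = active_windows(rows_left), active_windows(rows_right)
    return {
        k: (min(wl[k][0], wr[k][0]), max(wl[k][1], wr[k][1]))
        for k in sorted(set(wl) & set(wr))
    }


def mean_active_envelope(
    env: np.ndarray,
    cs: CycleSet,
    rows: pd.DataFrame,
    N: int = 100,
    windows: dict[int, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average envelope over the active window, resampled to N points.

    Returns ``(mean_curve, cycle_matrix)`` where ``cycle_matrix`` has one
    row of N points per valid cycle (the per-cycle resampled windows used
    both for averaging and for per-leg max normalisation).
    """
    if windows is None:
        windows = active_windows(rows)
    mat = _window_matrix(env, cs, windows, N)
    return mat.mean(axis=0), mat


def normalize_per_leg(
    mean_env: np.ndarray,
    cycle_matrix: np.ndarray | None = None,
    mode: str = "mean_peak",
) -> np.ndarray:
    """Normalise one leg's mean active envelope to its maximal value.

    ``mode="mean_peak"`` (default) divides by the peak of the
    across-cycle mean envelope, so the normalised curve tops out at
    exactly 1; ``mode="cycle_max"`` divides by the maximal envelope
    value observed across the leg's individual cycles (necessarily >=
    the mean's peak, so the normalised mean stays <= 1).  The default is
    preferred for side comparisons because the individual-cycle maximum
    is an extreme-value statistic whose ~3% sampling fluctuation is
    independent between legs and would masquerade as an amplitude
    asymmetry.
    """
    mean_env = np.asarray(mean_env, dtype=np.float64)
    if mode == "mean_peak":
        peak = float(mean_env.max())
    elif mode == "cycle_max":
        if cycle_matrix is None:
            raise SessionError("cycle_max normalisation needs the cycle matrix")
        peak = float(cycle_matrix.max())
    else:
        raise SessionError(f"unknown normalisation mode {mode!r}")
    if peak <= 0:
        raise SessionError("cannot normalise: maximal envelope value is zero")
    return mean_env / peak


def bilateral_stats(
    left_norm: np.ndarray, right_norm: np.ndarray, muscle: str = ""
) -> SymmetryResult:
    """Pearson R and OLS slope (left on right) tested against unity."""
    left = np.asarray(left_norm, dtype=np.float64)
    right = np.asarray(right_norm, dtype=np.float64)
    if left.shape != right.shape or left.size < 3:
        raise SessionError("need two equal-length sequences of >= 3 points")
    if np.std(left) == 0 or np.std(right) == 0:
        raise SessionError("zero variance: correlation and slope undefined")
    n = left.size
    r, r_p = sst.pearsonr(right, left)
    fit = sst.linregress(right, left)
    if fit.stderr == 0.0:  # perfect fit: t undefined at SE 0
        p_unity = 1.0 if fit.slope == 1.0 else 0.0
        return SymmetryResult(
            muscle, float(r), float(r_p), float(fit.slope), 0.0, p_unity,
            float(fit.intercept), n, degenerate=True,
        )
    t = (fit.slope - 1.0) / fit.stderr
    p_unity = 2.0 * sst.t.sf(abs(t), n - 2)
    return SymmetryResult(
        muscle, float(r), float(r_p), float(fit.slope), float(fit.stderr),
        float(p_unity), float(fit.intercept), n,
    )


def _jackknife_slope_test(
    mat_l: np.ndarray, mat_r: np.ndarray
) -> tuple[float, float] | None:
    """Delete-one-cycle jackknife SE and p for H0: slope = 1.

    The N grid points of the paired curves are strongly autocorrelated
    (they come from 5 Hz-smoothed envelopes), so the naive OLS slope SE
    is badly anti-conservative.  Rowing cycles, however, are independent
    replicates: leaving out one cycle at a time, re-averaging,
    re-normalising and re-fitting gives an honest sampling distribution
    for the slope.  Returns None when fewer than 3 cycles are available.
    """
    n = mat_l.shape[0]
    if n < 3:
        return None

    def _slope(mask: np.ndarray) -> float:
        l = mat_l[mask].mean(axis=0)
        r = mat_r[mask].mean(axis=0)
        if l.max() <= 0 or r.max() <= 0 or np.std(l) == 0 or np.std(r) == 0:
            return np.nan
        return sst.linregress(r / r.max(), l / l.max()).slope

    full = _slope(np.ones(n, dtype=bool))
    jk = np.array([_slope(np.arange(n) != i) for i in range(n)])
    if np.isnan(full) or np.isnan(jk).any():
        return None
    se = float(np.sqrt((n - 1) / n * np.sum((jk - jk.mean()) ** 2)))
    if se == 0.0:
        return (0.0, 1.0 if full == 1.0 else 0.0)
    t = (full - 1.0) / se
    return (se, float(2.0 * sst.t.sf(abs(t), n - 1)))


def bilateral_symmetry(
    env_left: np.ndarray,
    env_right: np.ndarray,
    cs: CycleSet,
    rows_left: pd.DataFrame,
    rows_right: pd.DataFrame,
    N: int = 100,
    muscle: str = "",
) -> tuple[SymmetryResult, np.ndarray, np.ndarray]:
    """End-to-end left/right comparison for one muscle.

    Pairs the two sides over the per-cycle union of active windows,
    normalises each side to its own maximum, and returns the symmetry
    statistics with the two normalised mean curves.  The slope-vs-unity
    p-value (and SE) use the cycle-jackknife test, which is calibrated
    for the autocorrelated curve points; R and the slope point estimate
    come from the plain regression of left on right.
    """
    win = union_windows(rows_left, rows_right)
    if not win:
        raise SessionError(f"no cycles valid on both sides for {muscle or 'muscle'}")
    mean_l, mat_l = mean_active_envelope(env_left, cs, rows_left, N, windows=win)
    mean_r, mat_r = mean_active_envelope(env_right, cs, rows_right, N, windows=win)
    norm_l = normalize_per_leg(mean_l, mat_l)
    norm_r = normalize_per_leg(mean_r, mat_r)
    res = bilateral_stats(norm_l, norm_r, muscle=muscle)
    jk = _jackknife_slope_test(mat_l, mat_r)
    if jk is not None and not res.degenerate:
        se, p = jk
        res = SymmetryResult(
            muscle=res.muscle, R=res.R, R_p=res.R_p, slope=res.slope,
            slope_se=se, slope_p_vs_unity=p, intercept=res.intercept,
            n_points=res.n_points, degenerate=False,
        )
    return res, norm_l, norm_r


def symmetry_table(results: list[SymmetryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "muscle": r.muscle,
                "R": r.R,
                "R_p": r.R_p,
                "slope": r.slope,
                "slope_se": r.slope_se,
                "slope_p_vs_unity": r.slope_p_vs_unity,
                "n_points": r.n_points,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
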