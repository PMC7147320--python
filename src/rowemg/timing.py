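"""Rest-baseline activity detection and cycle-relative timing.

The silence baseline is defined from a rest recording as k times the
standard deviation of the rest EMG envelope (k = 5 by default).  Because
the envelope of rest-level noise fluctuates around a positive mean level
(E|N(0, s^2)| = sqrt(2/pi) * s) with a much smaller SD, the *detection
threshold* applied to trial envelopes adds the rest-envelope mean to
that baseline margin by default: a threshold below the rest mean would
never be crossed downward and no silencing could be detected.  The pure
k*SD variant (no mean term) remains available via
``TimingParams(include_rest_mean=False)``.

Supra-threshold runs are located over the whole record, their start and
end refined by linear interpolation between the bracketing envelope
samples, and each run is attributed to the rowing cycle containing its
midpoint.  Per cycle, the activation onset is the start of the first
attributed run and the silencing the end of the last one, both in % of
the cycle (negative when recruitment precedes the catch, above 100% when
silencing outlasts it).  The duration of activity is the algebraic sum
of the attributed supra-threshold intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import CycleSet, to_cycle_pct
from .signal_model import SessionError


@dataclass(frozen=True)
class TimingParams:
    """Parameters of the activity detector.

    baseline_k
        multiplier on the rest-envelope SD (default 5).
    include_rest_mean
        add the rest-envelope mean to the detection threshold (default
        True; see module docstring).
    search_anchor
        reference instant of the detection convention; only "finish"
        (activity searched around each cycle's finish-to-finish span) is
        supported.
    debounce_pct
        minimum supra-threshold run length in % of cycle; runs shorter
        than this are ignored (default 0: no debounce).
    """

    baseline_k: float = 5.0
    include_rest_mean: bool = True
    search_anchor: str = "finish"
    debounce_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_k <= 0:
            raise SessionError("baseline_k must be positive")
        if self.search_anchor != "finish":
            raise SessionError(f"unsupported search_anchor {self.search_anchor!r}")


def baseline(rest_env: np.ndarray, k: float = 5.0) -> float:
    """Baseline margin: k times the SD of the rest envelope.

    A flat rest envelope yields 0 with a warning (any non-zero trial
    envelope sample would then count as activity).
    """
    rest_env = np.asarray(rest_env, dtype=np.float64)
    sd = float(np.std(rest_env))
    if sd == 0.0:
        warnings.warn("flat rest envelope: baseline is 0", stacklevel=2)
    return k * sd


def detection_threshold(
    rest_env: np.ndarray, params: TimingParams | None = None
) -> float:
    """Threshold in uV applied to trial envelopes.

    rest-envelope mean + baseline margin by default; the pure k*SD
    baseline when ``include_rest_mean`` is off.
    """
    params = params or TimingParams()
    thr = baseline(rest_env, params.baseline_k)
    if params.include_rest_mean:
        thr += float(np.mean(rest_env))
    return thr


def supra_threshold_runs(env: np.ndarray, threshold: float) -> list[tuple[float, float]]:
    """Runs where env >= threshold, with interpolated sub-sample bounds.

    Crossing events are transitions between strictly-below and
    at-or-above samples; an exact-equality plateau starts a run at its
    earliest sample and ends it at its latest.  Runs touching the record
    edges start/end exactly at the edge sample.
    """
    env = np.asarray(env, dtype=np.float64)
    mask = env >= threshold
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    ups = np.flatnonzero(d == 1)  # env[i] < thr <= env[i+1]
    downs = np.flatnonzero(d == -1)  # env[j] >= thr > env[j+1]
    starts = [
        i + (threshold - env[i]) / (env[i + 1] - env[i]) for i in ups
    ]
    ends = [
        j + (env[j] - threshold) / (env[j] - env[j + 1]) for j in downs
    ]
    if mask[0]:
        starts.insert(0, 0.0)
    if mask[-1]:
        ends.append(float(env.size - 1))
    assert len(starts) == len(ends)
    return list(zip(starts, ends))


def detect_activity(
    env: np.ndarray,
    cs: CycleSet,
    threshold: float,
    params: TimingParams | None = None,
) -> pd.DataFrame:
    """Per-cycle activation onset, silencing, segments and duration.

    Returns one row per cycle with columns ``cycle``, ``onset_pct``,
    ``silencing_pct``, ``duration_pct``, ``segments`` (list of
    (start_pct, end_pct)) and ``flag``: "ok", "silent" (envelope never
    reaches threshold in the cycle), or "always_on" (a single run covers
    the whole cycle).  Flagged cycles carry NaN timing and are excluded
    from aggregation but stay visible in the quality report.
    """
    params = params or TimingParams()
    if threshold <= 0:
        raise SessionError("detection threshold must be positive")
    bounds = cs.bounds.astype(float)
    runs = supra_threshold_runs(env, threshold)

    per_cycle: dict[int, list[tuple[float, float]]] = {k: [] for k in range(cs.n_cycles)}
    always_on = set()
    for start, end in runs:
        # cycles fully inside the run never cross the threshold: always-on
        covered = [
            k for k in range(cs.n_cycles)
            if start <= bounds[k] and end >= bounds[k + 1]
        ]
        always_on.update(covered)
        mid = 0.5 * (start + end)
        k = int(np.searchsorted(bounds, mid, side="right")) - 1
        if not (0 <= k < cs.n_cycles):
            continue
        if params.debounce_pct > 0:
            span = 100.0 * (end - start) / (bounds[k + 1] - bounds[k])
            if span < params.debounce_pct:
                continue
        per_cycle[k].append((start, end))

    rows = []
    for k in range(cs.n_cycles):
        c, nc = bounds[k], bounds[k + 1]
        segs_t = sorted(per_cycle[k])
        if k in always_on:
            rows.append((k, np.nan, np.nan, np.nan, [], "always_on"))
            continue
        if not segs_t:
            rows.append((k, np.nan, np.nan, np.nan, [], "silent"))
            continue
        segs = [
            (to_cycle_pct(s, c, nc), to_cycle_pct(e, c, nc)) for s, e in segs_t
        ]
        onset = segs[0][0]
        silencing = segs[-1][1]
        dur = float(sum(e - s for s, e in segs))
        rows.append((k, onset, silencing, dur, segs, "ok"))
    return pd.DataFrame(
        rows,
        columns=["cycle", "onset_pct", "silencing_pct", "duration_pct", "segments", "flag"],
    )


def duration_summary(rows: pd.DataFrame) -> dict[str, float]:
    """Mean and sample SD of per-cycle activity duration over valid cycles."""
    ok = rows.loc[rows["flag"] == "ok", "duration_pct"]
    if ok.empty:
        return {"n_cycles": 0, "mean_pct": float("nan"), "sd_pct": float("nan")}
    return {
        "n_cycles": int(ok.size),
        "mean_pct": float(ok.mean()),
        "sd_pct": 0.0 if ok.size == 1 else float(ok.std(ddof=1)),
    }


def aggregate_timing(rows: pd.DataFrame) -> pd.DataFrame:
    """Summarize timing per (muscle, side, stroke_rate) and pooled.

    ``rows`` is the concatenation of per-channel detect_activity outputs
    with added ``muscle``, ``side`` and ``stroke_rate`` columns.  The
    pooled rows (stroke_rate = "pooled") average over all valid cycles of
    the three stroke rates, mirroring the across-rate averaging of onset
    values.  Cycle and exclusion counts are reported per group; groups
    with no valid cycles are omitted with a warning.
    """
    required = {"muscle", "side", "stroke_rate", "onset_pct", "silencing_pct", "duration_pct", "flag"}
    missing = required - set(rows.columns)
    if missing:
        raise SessionError(f"timing rows missing columns: {sorted(missing)}")

    def _summarize(g: pd.DataFrame) -> pd.Series | None:
        ok = g[g["flag"] == "ok"]
        n = len(ok)
        out = {"n_cycles": n, "n_excluded": int(len(g) - n)}
        for col in ("onset_pct", "silencing_pct", "duration_pct"):
            out[col.replace("_pct", "_mean")] = float(ok[col].mean()) if n else np.nan
            out[col.replace("_pct", "_sd")] = (
                float(ok[col].std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan)
            )
        return pd.Series(out)

    parts = []
    for keys, g in rows.groupby(["muscle", "side", "stroke_rate"], sort=True):
        s = _summarize(g)
        if s["n_cycles"] == 0:
            warnings.warn(f"group {keys} has no valid cycles; omitted", stacklevel=2)
            continue
        parts.append(
            s.to_frame().T.assign(muscle=keys[0], side=keys[1], stroke_rate=keys[2])
        )
    for keys, g in rows.groupby(["muscle", "side"], sort=True):
        s = _summarize(g)
        if s["n_cycles"] == 0:
            continue
        parts.append(
            s.to_frame().T.assign(muscle=keys[0], side=keys[1], stroke_rate="pooled")
        )
    if not parts:
        raise SessionError("no valid cycles in any group")
    out = pd.concat(parts, ignore_index=True)
    cols = [
        "muscle", "side", "stroke_rate", "n_cycles", "n_excluded",
        "onset_mean", "onset_sd", "silencing_mean", "silencing_sd",
        "duration_mean", "duration_sd",
    ]
    return out[cols]
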