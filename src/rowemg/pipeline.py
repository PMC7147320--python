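"""End-to-end analysis pipeline: envelopes -> cycles -> timing -> symmetry -> stats.

`analyze_recording` runs the per-trial analysis in memory;
`run_pipeline` drives it from a single YAML/JSON config (the only place
parameters are set) and writes the report files:

    timing_cycles.csv    per cycle x channel onset/silencing/duration
    timing_summary.csv   per muscle/side/stroke-rate means and SDs
    symmetry.csv         per-muscle bilateral R, slope and slope-vs-unity p
    stats.json           gates, ANOVA effects, pooling decision
    run_log.json         every numeric parameter, exclusions, seeds

`run_synth_demo` generates synthetic trials at the three protocol stroke
rates, analyses them, and appends a ground-truth recovery error table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_stats as gs
from .cycles import CycleSet, detect_cycles
from .envelope import EnvelopeParams, envelope
from .signal_model import (
    Finding,
    Recording,
    RestRecording,
    SessionError,
    read_rest,
    read_session,
    validate_recording,
)
from .symmetry import SymmetryResult, bilateral_symmetry, symmetry_table
from .synth import SessionSpec, gen_session
from .timing import TimingParams, aggregate_timing, detect_activity, detection_threshold


@dataclass
class PipelineConfig:
    """All parameters of a pipeline run; loadable from YAML/JSON."""

    sessions: list[str] = field(default_factory=list)
    out: str = "rowemg_out"
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    timing: TimingParams = field(default_factory=TimingParams)
    min_prominence_mm: float = 100.0
    min_cycle_s: float | None = None
    n_norm: int = 100
    excluded_channels: list[str] = field(default_factory=list)
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.envelope, dict):
            self.envelope = EnvelopeParams(**self.envelope)
        if isinstance(self.timing, dict):
            self.timing = TimingParams(**self.timing)
        if self.n_norm < 3:
            raise SessionError("n_norm must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SessionError(f"config {path} did not parse to a mapping")
        kwargs = dict(raw)
        if "envelope" in kwargs:
            kwargs["envelope"] = EnvelopeParams(**kwargs["envelope"])
        if "timing" in kwargs:
            kwargs["timing"] = TimingParams(**kwargs["timing"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SessionError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_log(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class AnalysisResult:
    """Per-trial analysis output."""

    findings: list[Finding]
    cycle_set: CycleSet
    rows: pd.DataFrame  # per cycle x channel timing
    thresholds: dict[str, float]
    envelopes: dict[str, np.ndarray]
    symmetry: list[SymmetryResult]
    sym_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    excluded: list[str]


def analyze_recording(
    rec: Recording,
    rest: RestRecording,
    env_params: EnvelopeParams | None = None,
    timing_params: TimingParams | None = None,
    n_norm: int = 100,
    min_prominence_mm: float = 100.0,
    min_cycle_s: float | None = None,
    excluded_channels: tuple[str, ...] = (),
) -> AnalysisResult:
    """Full single-trial analysis.

    Channels are excluded when flagged in metadata, listed in
    ``excluded_channels``, or found flat / NaN-ridden by the automatic
    quality screen.  Raises :class:`SessionError` if no analyzable
    channel remains or no complete cycle is found.
    """
    env_params = env_params or EnvelopeParams()
    timing_params = timing_params or TimingParams()
    if rec.handle is None:
        raise SessionError("cycle analysis requires a handle trace")

    findings = validate_recording(rec)
    bad = {f.channel for f in findings if f.kind in ("flat", "nan")}
    excluded = sorted(
        {c.label for c in rec.channels if c.excluded}
        | (bad & {c.label for c in rec.channels})
        | set(excluded_channels)
    )
    keep = [c for c in rec.channels if c.label not in excluded]
    if not keep:
        raise SessionError("no analyzable channels (all excluded or flagged)")

    cs = detect_cycles(
        rec.handle,
        rec.fs,
        min_cycle_s=min_cycle_s,
        min_prominence_mm=min_prominence_mm,
        stroke_rate_nominal=rec.stroke_rate_nominal,
    )

    rest_labels = [c.label for c in rest.channels] if rest.channels else []
    thresholds: dict[str, float] = {}
    envelopes: dict[str, np.ndarray] = {}
    parts = []
    for c in keep:
        i = rec.channel_index(c.muscle, c.side)
        j = rest_labels.index(c.label) if rest_labels else i
        rest_env = envelope(rest.emg[j], rest.fs, env_params)
        thr = detection_threshold(rest_env, timing_params)
        env = envelope(rec.emg[i], rec.fs, env_params)
        rows = detect_activity(env, cs, thr, timing_params)
        rows = rows.assign(
            muscle=c.muscle, side=c.side, stroke_rate=rec.stroke_rate_nominal
        )
        thresholds[c.label] = thr
        envelopes[c.label] = env
        parts.append(rows)
    all_rows = pd.concat(parts, ignore_index=True)

    sym_results: list[SymmetryResult] = []
    sym_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    muscles = sorted({c.muscle for c in keep})
    for m in muscles:
        labels = {s: f"{m}_{s}" for s in ("left", "right")}
        if not all(l in envelopes for l in labels.values()):
            continue
        rows_l = all_rows[(all_rows.muscle == m) & (all_rows.side == "left")]
        rows_r = all_rows[(all_rows.muscle == m) & (all_rows.side == "right")]
        try:
            res, norm_l, norm_r = bilateral_symmetry(
                envelopes[labels["left"]],
                envelopes[labels["right"]],
                cs,
                rows_l,
                rows_r,
                N=n_norm,
                muscle=m,
            )
        except SessionError:
            continue
        sym_results.append(res)
        sym_curves[m] = (norm_l, norm_r)

    return AnalysisResult(
        findings=findings,
        cycle_set=cs,
        rows=all_rows,
        thresholds=thresholds,
        envelopes=envelopes,
        symmetry=sym_results,
        sym_curves=sym_curves,
        excluded=excluded,
    )


def _stats_report(rows: pd.DataFrame, outcome: str = "onset_pct") -> dict:
    """Gates plus ANOVA effects on per-cycle timing values.

    With a single trial per stroke rate the rowing cycle is the repeated
    unit (muscle and side are within-cycle factors); stroke rate is then
    analysed per rate.  With several subjects the subject is the unit.
    """
    ok = rows[rows["flag"] == "ok"].copy()
    report: dict = {"outcome": outcome}
    groups = {
        f"{m}_{s}": g[outcome].to_numpy()
        for (m, s), g in ok.groupby(["muscle", "side"])
    }
    ng = gs.normality_gate(groups)
    report["normality"] = {
        "passed": ng.passed,
        "min_p": min(ng.p_values.values()) if ng.p_values else None,
        "skipped": ng.skipped,
        "degenerate": ng.degenerate,
    }
    try:
        W, p = gs.variance_gate(groups)
        report["levene"] = {"W": W, "p": p}
    except SessionError as e:
        report["levene"] = {"error": str(e)}

    per_rate = {}
    for rate, g in ok.groupby("stroke_rate"):
        tbl = g.rename(columns={"cycle": "subject"})[
            ["subject", "muscle", "side", outcome]
        ].copy()
        # keep only cycles observed for every muscle x side (balanced units)
        n_cells = tbl.groupby("subject").size()
        full = n_cells[n_cells == n_cells.max()].index
        tbl = tbl[tbl["subject"].isin(full)]
        try:
            eff = gs.anova_muscle_side(tbl, outcome)
            per_rate[str(rate)] = eff.drop(columns="degenerate").to_dict("records")
        except (SessionError, ValueError, KeyError) as e:
            per_rate[str(rate)] = {"error": str(e)}
    report["anova_by_rate"] = per_rate
    return report


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default, sort_keys=True))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _plot_reports(out: Path, summary: pd.DataFrame, results: list[AnalysisResult]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pooled = summary[summary.stroke_rate == "pooled"]
    fig, ax = plt.subplots(figsize=(7, 5))
    muscles = sorted(pooled.muscle.unique())
    for i, m in enumerate(muscles):
        for side, dy, color in (("left", 0.15, "k"), ("right", -0.15, "0.5")):
            row = pooled[(pooled.muscle == m) & (pooled.side == side)]
            if row.empty:
                continue
            r = row.iloc[0]
            ax.errorbar(
                [r.onset_mean, r.silencing_mean], [i + dy] * 2,
                xerr=[r.onset_sd, r.silencing_sd],
                fmt="s-" if side == "left" else "o-", color=color, capsize=2,
            )
    ax.set_yticks(range(len(muscles)), muscles)
    ax.set_xlabel("% of rowing cycle (catch = 0)")
    ax.set_title("activation onset (left marker) to silencing (right marker)")
    fig.tight_layout()
    fig.savefig(out / "timing.png", dpi=120)
    plt.close(fig)

    res = results[0]
    if res.sym_curves:
        n = len(res.sym_curves)
        fig, axes = plt.subplots(2, (n + 1) // 2, figsize=(3 * ((n + 1) // 2), 6))
        for ax, (m, (l, r)) in zip(np.ravel(axes), sorted(res.sym_curves.items())):
            ax.plot(r, l, "o", ms=2)
            lim = [0, 1.05]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_title(m, fontsize=8)
            ax.set_xlabel("right (norm.)", fontsize=7)
            ax.set_ylabel("left (norm.)", fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "symmetry.png", dpi=120)
        plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured analysis over the listed session containers."""
    if not cfg.sessions:
        raise SessionError("config lists no session containers")
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    results: list[AnalysisResult] = []
    all_rows = []
    for sid, spath in enumerate(cfg.sessions):
        rec = read_session(spath)
        rest = read_rest(spath)
        res = analyze_recording(
            rec,
            rest,
            env_params=cfg.envelope,
            timing_params=cfg.timing,
            n_norm=cfg.n_norm,
            min_prominence_mm=cfg.min_prominence_mm,
            min_cycle_s=cfg.min_cycle_s,
            excluded_channels=tuple(cfg.excluded_channels),
        )
        results.append(res)
        all_rows.append(res.rows.assign(session=Path(spath).name, session_id=sid))

    rows = pd.concat(all_rows, ignore_index=True)
    summary = aggregate_timing(rows)

    rows.drop(columns=["segments"]).to_csv(out / "timing_cycles.csv", index=False)
    summary.to_csv(out / "timing_summary.csv", index=False)

    sym_all = [r for res in results for r in res.symmetry]
    symmetry_table(sym_all).to_csv(out / "symmetry.csv", index=False)

    stats = {
        "onset": _stats_report(rows, "onset_pct"),
        "silencing": _stats_report(rows, "silencing_pct"),
        "duration": _stats_report(rows, "duration_pct"),
    }
    _write_json(out / "stats.json", stats)

    log = {
        "config": cfg.to_log(),
        "sessions": list(cfg.sessions),
        "excluded_channels": sorted({e for r in results for e in r.excluded}),
        "findings": [
            {"channel": f.channel, "kind": f.kind, "detail": f.detail}
            for r in results
            for f in r.findings
        ],
        "thresholds_uv": {
            f"session{i}": r.thresholds for i, r in enumerate(results)
        },
        "n_cycles": [r.cycle_set.n_cycles for r in results],
    }
    _write_json(out / "run_log.json", log)

    if cfg.plots:
        _plot_reports(out, summary, results)
    return out


def run_synth_demo(
    out: str | Path,
    base_spec: SessionSpec | None = None,
    rates: tuple[float, ...] = (18.0, 24.0, 28.0),
    seed: int = 0,
    plots: bool = False,
    n_norm: int = 100,
) -> dict:
    """Generate, analyse and score synthetic trials at the protocol rates.

    Returns the report dict (also written to ``<out>/demo_report.json``)
    whose ``recovery`` table compares detected onset/silencing means with
    the generator's ground truth per channel and stroke rate, including
    the maximum absolute error.
    """
    import dataclasses as dc

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    base = base_spec or SessionSpec()

    all_rows = []
    results = []
    recovery = []
    for k, spm in enumerate(rates):
        spec = dc.replace(base, spm=spm, seed=seed + 1000 * k)
        rec, rest, truth = gen_session(spec)
        res = analyze_recording(rec, rest, n_norm=n_norm)
        rows = res.rows
        all_rows.append(rows.assign(session=f"synth_{spm:g}spm"))
        results.append(res)
        for (m, s), burst in spec.bursts.items():
            sub = rows[(rows.muscle == m) & (rows.side == s) & (rows.flag == "ok")]
            if sub.empty:
                continue
            recovery.append(
                {
                    "stroke_rate": spm,
                    "muscle": m,
                    "side": s,
                    "true_onset_pct": burst.onset_pct,
                    "detected_onset_pct": float(sub.onset_pct.mean()),
                    "true_silencing_pct": burst.onset_pct + burst.span_pct,
                    "detected_silencing_pct": float(sub.silencing_pct.mean()),
                    "n_cycles": int(len(sub)),
                }
            )

    rows = pd.concat(all_rows, ignore_index=True)
    summary = aggregate_timing(rows)
    rows.drop(columns=["segments"]).to_csv(out / "timing_cycles.csv", index=False)
    summary.to_csv(out / "timing_summary.csv", index=False)
    sym_all = [r for res in results for r in res.symmetry]
    symmetry_table(sym_all).to_csv(out / "symmetry.csv", index=False)
    _write_json(out / "stats.json", {"onset": _stats_report(rows, "onset_pct")})

    rec_df = pd.DataFrame(recovery)
    rec_df["onset_error_pct"] = rec_df.detected_onset_pct - rec_df.true_onset_pct
    rec_df["silencing_error_pct"] = (
        rec_df.detected_silencing_pct - rec_df.true_silencing_pct
    )
    report = {
        "rates": list(rates),
        "seed": seed,
        "max_abs_onset_error_pct": float(rec_df.onset_error_pct.abs().max()),
        "max_abs_silencing_error_pct": float(rec_df.silencing_error_pct.abs().max()),
        "recovery": rec_df.to_dict("records"),
    }
    rec_df.to_csv(out / "recovery.csv", index=False)
    _write_json(out / "demo_report.json", report)
    if plots:
        _plot_reports(out, summary, results)
    return report
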