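"""Synthetic rowing sessions with known ground-truth muscle timing.

The generator emulates the statistical structure the analysis pipeline
assumes rather than the physiology that produces it:

* **Handle position** is a quasi-periodic trace built from a raised-cosine
  drive segment (catch -> finish) and a slower raised-cosine recovery
  (finish -> next catch), so every cycle has exactly one global minimum
  (catch) and one maximum (finish).  A half-recovery lead-in and a
  half-drive lead-out make all catches and finishes interior extrema.
* **EMG channels** are band-limited (20-400 Hz) zero-mean Gaussian noise
  whose instantaneous standard deviation is ``rest_noise_uv`` plus a
  burst profile: amplitude modulation of a noise carrier, not an added
  deterministic waveform, so the rectified-envelope statistics downstream
  resemble real surface EMG.
* **Burst timing** is expressed in % of the rowing cycle.  Negative
  onsets place recruitment in the preceding recovery (activity "just
  before catch").  Cycle-duration jitter rescales burst timing
  proportionally; an independent additive timing jitter (in % of cycle)
  models cycle-to-cycle neuromuscular variability of onset/offset.

Everything is reproducible: identical ``SessionSpec`` (including seed)
produces bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_model import (
    MUSCLES,
    SIDES,
    ChannelMeta,
    Recording,
    RestRecording,
    SessionError,
)

#: nominal activation onset / silencing (% of cycle, catch = 0) for the
#: default montage; chosen to mirror the qualitative picture in elite
#: rowing: quadriceps/triceps surae recruited just before catch and
#: silenced around the finish, rectus femoris active longest (51% of the
#: cycle) and silenced after the finish, biceps femoris briefest (22%),
#: semitendinosus recruited earliest, tibialis anterior the only muscle
#: active within recovery.
DEFAULT_TIMING: dict[str, tuple[float, float]] = {
    "rectus_femoris": (-5.0, 46.0),
    "vastus_lateralis": (-5.0, 36.0),
    "vastus_medialis": (-5.0, 37.0),
    "semitendinosus": (-12.0, 28.0),
    "biceps_femoris": (5.0, 27.0),
    "gastrocnemius_medialis": (-3.0, 30.0),
    "soleus": (-3.0, 32.0),
    "tibialis_anterior": (55.0, 90.0),
}


@dataclass(frozen=True)
class BurstSpec:
    """One channel's activity burst per rowing cycle.

    ``onset_pct`` may be negative (recruitment before the catch).  The
    active span is ``(offset_pct - onset_pct) mod 100`` and must lie in
    (0, 100).  The default shape is a trapezoid whose rise/fall ramps
    last ``ramp_pct`` of the *cycle* (default 5%, i.e. a rise time
    comparable to the 5 Hz envelope smoother's resolution): the ramp
    feet make the nominal onset/offset operationally well-defined for a
    threshold detector, while edges much sharper than the smoother
    cannot be resolved and edges much smoother (``hann``) leave the
    nominal onset ill-defined at threshold level.
    """

    onset_pct: float
    offset_pct: float
    peak_uv: float = 100.0
    shape: str = "trapezoid"
    ramp_pct: float = 5.0

    def __post_init__(self) -> None:
        if not (-50.0 <= self.onset_pct < 100.0):
            raise SessionError(f"onset_pct {self.onset_pct} outside [-50, 100)")
        if self.shape not in ("hann", "trapezoid"):
            raise SessionError(f"unknown burst shape {self.shape!r}")
        if self.peak_uv < 0:
            raise SessionError("peak_uv must be non-negative")
        span = self.span_pct
        if not (0.0 < span < 100.0):
            raise SessionError(f"active span {span}% outside (0, 100)")

    @property
    def span_pct(self) -> float:
        return (self.offset_pct - self.onset_pct) % 100.0

    def window(self, u: np.ndarray) -> np.ndarray:
        """Burst profile on normalized position u in [0, 1] of the span."""
        u = np.clip(u, 0.0, 1.0)
        if self.shape == "hann":
            return np.sin(np.pi * u) ** 2
        # ramp_pct is in % of cycle; normalize by the span, keep a plateau
        r = min(self.ramp_pct / self.span_pct, 0.45)
        return np.clip(np.minimum(u / r, (1.0 - u) / r), 0.0, 1.0)


def default_bursts(peak_uv: float = 100.0) -> dict[tuple[str, str], BurstSpec]:
    """Burst map for the full 16-channel montage with the default timing."""
    return {
        (m, s): BurstSpec(*DEFAULT_TIMING[m], peak_uv=peak_uv)
        for m in MUSCLES
        for s in SIDES
    }


@dataclass
class SessionSpec:
    """Study conditions for one synthetic trial.

    Defaults reflect the emulated protocol: 2048 Hz sampling, >= 30
    consecutive strokes per trial at 18/24/28 spm (24 by default),
    cycle-duration jitter of 5% of nominal and burst-timing jitter of 3%
    of cycle, a ~1 m handle excursion, and a rest noise floor of 3 uV.
    """

    spm: float = 24.0
    n_cycles: int = 30
    fs: float = 2048.0
    drive_fraction: float = 0.4
    jitter_pct: float = 5.0
    timing_jitter_pct: float = 3.0
    rest_noise_uv: float = 3.0
    handle_amplitude_mm: float = 1000.0
    handle_noise_mm: float = 0.0
    #: per-cycle timing jitter shared by the two sides of a muscle
    #: (bilateral common drive); set False for side-independent jitter
    bilateral_common_jitter: bool = True
    bursts: dict[tuple[str, str], BurstSpec] = field(default_factory=default_bursts)
    side_gain: dict[str, float] = field(
        default_factory=lambda: {"left": 1.0, "right": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise SessionError("n_cycles must be >= 1")
        if self.fs < 1000.0:
            raise SessionError(
                f"fs={self.fs} Hz cannot represent the 20-400 Hz EMG band"
            )
        if not (0.0 < self.drive_fraction < 1.0):
            raise SessionError("drive_fraction must be in (0, 1)")
        if any(g <= 0 for g in self.side_gain.values()):
            raise SessionError("side gains must be positive")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.spm

    def channels(self) -> list[ChannelMeta]:
        return [ChannelMeta(m, s) for (m, s) in self.bursts]


@dataclass
class GroundTruth:
    """Oracle timing written by the generator.

    ``cycle_bounds`` holds the n_cycles+1 catch sample indices delimiting
    the n_cycles complete cycles; ``catch_times`` are the n_cycles
    cycle-start catches and ``finish_times`` the n_cycles finishes.
    ``true_onset_pct``/``true_offset_pct`` are the nominal (spec) values
    per channel; ``cycle_onset_pct``/``cycle_offset_pct`` include the
    per-cycle timing jitter actually applied.
    """

    cycle_bounds: np.ndarray
    finish_times: np.ndarray
    durations_s: np.ndarray
    fs: float
    true_onset_pct: dict[str, float] = field(default_factory=dict)
    true_offset_pct: dict[str, float] = field(default_factory=dict)
    cycle_onset_pct: dict[str, np.ndarray] = field(default_factory=dict)
    cycle_offset_pct: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def catch_times(self) -> np.ndarray:
        return self.cycle_bounds[:-1]

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds) - 1


def _channel_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, label-stable stream per channel."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _cycle_sample_counts(spec: SessionSpec, rng: np.random.Generator) -> np.ndarray:
    nominal = spec.fs * spec.cycle_s
    z = np.clip(rng.standard_normal(spec.n_cycles), -3.0, 3.0)
    counts = np.rint(nominal * (1.0 + spec.jitter_pct / 100.0 * z)).astype(int)
    return np.maximum(counts, 4)


def gen_handle(
    spec: SessionSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Generate the handle-position trace and its ground-truth segmentation.

    Within each cycle the position rises from 0 (catch) to the full
    excursion (finish) over ``drive_fraction`` of the cycle and returns
    along a slower raised cosine.  With ``jitter_pct`` = 0 every cycle
    lasts exactly ``round(fs * 60/spm)`` samples.
    """
    rng = rng or _channel_rng(spec.seed, "handle")
    counts = _cycle_sample_counts(spec, rng)
    A = spec.handle_amplitude_mm

    n_rec_lead = max(int(round((1.0 - spec.drive_fraction) * spec.fs * spec.cycle_s / 2)), 2)
    n_drv_tail = max(int(round(spec.drive_fraction * spec.fs * spec.cycle_s / 2)), 2)

    # lead-in: second half of a recovery, ending exactly at the first catch
    full_rec = 2 * n_rec_lead
    i = np.arange(n_rec_lead)
    lead = A / 2 * (1 + np.cos(np.pi * (i + n_rec_lead) / full_rec))

    pieces = [lead]
    bounds = [n_rec_lead]
    finishes = []
    for n_k in counts:
        d_k = max(int(round(spec.drive_fraction * n_k)), 1)
        i = np.arange(n_k)
        drive = A / 2 * (1 - np.cos(np.pi * i[:d_k] / d_k))
        rec = A / 2 * (1 + np.cos(np.pi * (i[d_k:] - d_k) / (n_k - d_k)))
        pieces.append(np.concatenate([drive, rec]))
        finishes.append(bounds[-1] + d_k)
        bounds.append(bounds[-1] + n_k)

    # lead-out: first half of a drive, starting at the terminal catch
    i = np.arange(n_drv_tail)
    tail = A / 2 * (1 - np.cos(np.pi * i / (2 * n_drv_tail)))
    pieces.append(tail)

    pos = np.concatenate(pieces)
    if spec.handle_noise_mm > 0:
        pos = pos + rng.normal(0.0, spec.handle_noise_mm, size=pos.size)

    bounds = np.asarray(bounds)
    truth = GroundTruth(
        cycle_bounds=bounds,
        finish_times=np.asarray(finishes),
        durations_s=np.diff(bounds) / spec.fs,
        fs=spec.fs,
    )
    return pos, truth


def _bandlimited_noise(
    n: int, fs: float, rng: np.random.Generator, low: float = 20.0, high: float = 400.0
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [low, high] Hz."""
    if fs < 2 * high + 100:  # band must sit comfortably below Nyquist
        raise SessionError(f"fs={fs} Hz too low for the {low}-{high} Hz band")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_emg_channel(
    spec: SessionSpec,
    channel: ChannelMeta,
    truth: GroundTruth,
    n_samples: int | None = None,
) -> np.ndarray:
    """Generate one EMG channel (uV) on the timeline defined by ``truth``.

    The channel is zero-mean band-limited noise whose instantaneous SD is
    ``rest_noise_uv`` plus the burst profile (peak * shape window * side
    gain) positioned at the channel's onset/offset percentages of each
    cycle.  Per-cycle timing jitter actually applied is recorded into
    ``truth.cycle_onset_pct`` / ``truth.cycle_offset_pct``.
    """
    if n_samples is None:
        n_samples = int(truth.cycle_bounds[-1]) + max(
            int(round(spec.drive_fraction * spec.fs * spec.cycle_s / 2)), 2
        )
    rng = _channel_rng(spec.seed, channel.label)
    burst = spec.bursts.get((channel.muscle, channel.side))
    gain = spec.side_gain.get(channel.side, 1.0)

    sigma = np.full(n_samples, float(spec.rest_noise_uv))
    n_cyc = truth.n_cycles
    jitter_key = (
        f"timing_{channel.muscle}"
        if spec.bilateral_common_jitter
        else f"timing_{channel.label}"
    )
    jitter_rng = _channel_rng(spec.seed, jitter_key)
    shifts = (
        np.clip(jitter_rng.standard_normal(n_cyc), -3.0, 3.0) * spec.timing_jitter_pct
        if spec.timing_jitter_pct > 0
        else np.zeros(n_cyc)
    )
    if burst is not None and burst.peak_uv > 0:
        span = burst.span_pct
        onsets = burst.onset_pct + shifts
        offsets = onsets + span
        truth.true_onset_pct[channel.label] = burst.onset_pct
        truth.true_offset_pct[channel.label] = burst.offset_pct
        truth.cycle_onset_pct[channel.label] = onsets
        truth.cycle_offset_pct[channel.label] = offsets
        for k in range(n_cyc):
            b, nb = truth.cycle_bounds[k], truth.cycle_bounds[k + 1]
            n_k = nb - b
            start = b + onsets[k] / 100.0 * n_k
            width = span / 100.0 * n_k
            lo = max(int(np.floor(start)), 0)
            hi = min(int(np.ceil(start + width)) + 1, n_samples)
            if hi <= lo:
                continue
            u = (np.arange(lo, hi) - start) / width
            prof = burst.peak_uv * burst.window(u)
            sigma[lo:hi] = np.maximum(sigma[lo:hi], spec.rest_noise_uv + prof)
    carrier = _bandlimited_noise(n_samples, spec.fs, rng)
    # side gain scales the whole channel (burst and noise floor alike),
    # emulating electrode/impedance amplitude differences between legs
    return carrier * sigma * gain


def gen_rest(
    fs: float,
    duration_s: float = 5.0,
    rest_noise_uv: float = 3.0,
    seed: int = 0,
    channels: list[ChannelMeta] | None = None,
    side_gain: dict[str, float] | None = None,
) -> RestRecording:
    """Relaxed-sitting recording: band-limited noise at the rest noise floor.

    Each channel's sample SD equals ``rest_noise_uv`` exactly (the noise
    is renormalized after band-limiting), times the channel's side gain
    when one is given — the same electrode-level gain as in the trial, so
    baselines scale consistently.  ``rest_noise_uv = 0`` gives an
    all-zero recording.
    """
    if duration_s <= 0:
        raise SessionError("rest duration must be positive")
    channels = channels if channels is not None else [ChannelMeta(m, s) for m in MUSCLES for s in SIDES]
    n = int(round(duration_s * fs))
    emg = np.zeros((len(channels), n))
    if rest_noise_uv > 0:
        for i, c in enumerate(channels):
            rng = _channel_rng(seed, "rest_" + c.label)
            gain = (side_gain or {}).get(c.side, 1.0)
            emg[i] = _bandlimited_noise(n, fs, rng) * rest_noise_uv * gain
    return RestRecording(fs=fs, emg=emg, duration_s=duration_s, channels=channels)


def gen_session(
    spec: SessionSpec, rest_duration_s: float = 5.0
) -> tuple[Recording, RestRecording, GroundTruth]:
    """Assemble a full synthetic trial: EMG + handle + rest + ground truth."""
    handle, truth = gen_handle(spec)
    channels = spec.channels()
    emg = np.empty((len(channels), handle.size))
    for i, c in enumerate(channels):
        emg[i] = gen_emg_channel(spec, c, truth, n_samples=handle.size)
    rec = Recording(
        fs=spec.fs,
        emg=emg,
        handle=handle,
        channels=channels,
        stroke_rate_nominal=spec.spm,
    )
    rest = gen_rest(
        spec.fs,
        rest_duration_s,
        spec.rest_noise_uv,
        seed=spec.seed,
        channels=channels,
        side_gain=spec.side_gain,
    )
    return rec, rest, truth


def session_spec_for_rate(spec: SessionSpec, spm: float, seed: int) -> SessionSpec:
    """Copy of ``spec`` at another stroke rate with an independent seed."""
    return replace(spec, spm=spm, seed=seed)


def simulate_timing_table(
    n_subjects: int = 20,
    rates: tuple[float, ...] = (18.0, 24.0, 28.0),
    muscle_onsets: dict[str, float] | None = None,
    side_delta_pct: float = 0.0,
    subject_sd: float = 2.0,
    noise_sd: float = 3.0,
    outcome: str = "onset_pct",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a balanced timing-outcome table for statistical calibration.

    Draws one outcome value per (subject, stroke rate, muscle, side):
    muscle mean + subject random effect (SD ``subject_sd``) + Gaussian
    noise (SD ``noise_sd``, the within-cell cycle-to-cycle variability in
    % of cycle); ``side_delta_pct`` is added on the right side
    (0 = bilateral symmetric null).
    """
    if muscle_onsets is None:
        muscle_onsets = {m: DEFAULT_TIMING[m][0] for m in MUSCLES}
    rng = np.random.default_rng(seed)
    muscles = list(muscle_onsets)
    b_subj = rng.normal(0.0, subject_sd, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        for r in rates:
            for m in muscles:
                for side in SIDES:
                    val = (
                        muscle_onsets[m]
                        + b_subj[s]
                        + (side_delta_pct if side == "right" else 0.0)
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append((f"S{s:02d}", r, m, side, val))
    return pd.DataFrame(
        rows, columns=["subject", "stroke_rate", "muscle", "side", outcome]
    )
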