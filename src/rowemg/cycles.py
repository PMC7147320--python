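"""Rowing-cycle segmentation and time normalization.

Cycles are delimited by successive catches (handle-position minima); the
finish (maximum) falls inside each cycle.  The catch-anchored convention
maps a cycle onto 0-100%; instants during the preceding recovery are
reported as negative percentages of the current cycle, which avoids
circular-mean wraparound when averaging onsets that occur just before
the catch.

Extremum detection runs on a 5 Hz zero-phase low-passed copy of the
handle trace for noise robustness, then each extremum is refined on the
raw trace within +/-0.1 s to remove smoothing bias.  Incomplete first
and last cycles are always discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .envelope import EnvelopeParams, lowpass
from .signal_model import SessionError

#: the handle excursion in rowing is ~1 m; mm-scale ripple is noise
DEFAULT_PROMINENCE_MM = 100.0


@dataclass(frozen=True)
class CycleSet:
    """Ordered (catch, finish, next_catch) sample-index triples.

    Consecutive cycles share boundaries: the next-catch of cycle k is the
    catch of cycle k+1.
    """

    cycles: tuple[tuple[int, int, int], ...]
    fs: float

    def __post_init__(self) -> None:
        if len(self.cycles) < 1:
            raise SessionError("a CycleSet needs at least one complete cycle")
        for c, f, nc in self.cycles:
            if not (c < f < nc):
                raise SessionError(f"cycle ({c}, {f}, {nc}) not strictly ordered")
        for (_, _, nc), (c2, _, _) in zip(self.cycles, self.cycles[1:]):
            if nc != c2:
                raise SessionError("consecutive cycles must share boundaries")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def catches(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.cycles])

    @property
    def finishes(self) -> np.ndarray:
        return np.array([f for _, f, _ in self.cycles])

    @property
    def bounds(self) -> np.ndarray:
        """n_cycles + 1 catch indices delimiting the cycles."""
        return np.append(self.catches, self.cycles[-1][2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "catch_s": self.catches / self.fs,
                "finish_s": self.finishes / self.fs,
                "duration_s": np.diff(self.bounds) / self.fs,
            }
        )


@dataclass(frozen=True)
class NormalizedCycle:
    """One cycle's signal resampled onto exactly N points."""

    samples: np.ndarray
    cycle_index: int
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))


@dataclass(frozen=True)
class CycleDurations:
    durations_s: np.ndarray
    mean_s: float
    sd_s: float
    single_cycle: bool  # SD undefined for one cycle; reported as 0


def _refine_extremum(x: np.ndarray, idx: int, half: int, kind: str) -> int:
    lo = max(idx - half, 0)
    hi = min(idx + half + 1, x.size)
    seg = x[lo:hi]
    return lo + (int(np.argmin(seg)) if kind == "min" else int(np.argmax(seg)))


def detect_cycles(
    handle: np.ndarray,
    fs: float,
    min_cycle_s: float | None = None,
    min_prominence_mm: float = DEFAULT_PROMINENCE_MM,
    stroke_rate_nominal: float | None = None,
) -> CycleSet:
    """Segment the handle trace into complete catch->catch cycles.

    ``min_cycle_s`` defaults to half the nominal cycle duration when a
    nominal stroke rate is given, else 0.5 s.  Raises
    :class:`SessionError` when fewer than one complete cycle is found
    (e.g. a constant trace).
    """
    handle = np.asarray(handle, dtype=np.float64)
    if min_cycle_s is None:
        min_cycle_s = (
            0.5 * (60.0 / stroke_rate_nominal) if stroke_rate_nominal else 0.5
        )
    if min_cycle_s <= 0:
        raise SessionError("min_cycle_s must be positive")
    if handle.size < 8 or np.ptp(handle) < min_prominence_mm:
        raise SessionError("handle trace has no cycle-scale excursion")

    smooth = lowpass(handle, fs, EnvelopeParams())
    distance = max(int(min_cycle_s * fs), 1)
    minima, _ = sps.find_peaks(-smooth, prominence=min_prominence_mm, distance=distance)
    maxima, _ = sps.find_peaks(smooth, prominence=min_prominence_mm, distance=distance)
    if minima.size < 2 or maxima.size < 1:
        raise SessionError("fewer than one complete rowing cycle detected")

    half = int(round(0.1 * fs))
    minima = np.array(sorted({_refine_extremum(handle, i, half, "min") for i in minima}))
    maxima = np.array(sorted({_refine_extremum(handle, i, half, "max") for i in maxima}))

    cycles = []
    for c, nc in zip(minima, minima[1:]):
        between = maxima[(maxima > c) & (maxima < nc)]
        if between.size == 0:
            continue
        f = between[int(np.argmax(handle[between]))] if between.size > 1 else between[0]
        cycles.append((int(c), int(f), int(nc)))
    if not cycles:
        raise SessionError("fewer than one complete rowing cycle detected")
    return CycleSet(cycles=tuple(cycles), fs=fs)


def resample_cycle(
    x: np.ndarray, catch: int, next_catch: int, N: int = 100, cycle_index: int = 0, fs: float = 1.0
) -> NormalizedCycle:
    """Linearly interpolate one cycle's signal onto N equally spaced points.

    The grid covers [catch, next_catch): point j sits at
    catch + j * (next_catch - catch) / N, so resampling a cycle that is
    already N uniformly spaced samples is the identity.
    """
    if next_catch - catch < 2:
        raise SessionError("cycle shorter than 2 samples cannot be resampled")
    if not (0 <= catch and next_catch <= len(x)):
        raise SessionError("cycle bounds outside the signal")
    grid = catch + (next_catch - catch) * np.arange(N) / N
    vals = np.interp(grid, np.arange(len(x)), x)
    return NormalizedCycle(
        samples=vals, cycle_index=cycle_index, duration_s=(next_catch - catch) / fs
    )


def cycle_durations(cs: CycleSet) -> CycleDurations:
    """Per-cycle durations with mean and sample SD (ddof=1)."""
    d = np.diff(cs.bounds) / cs.fs
    single = d.size == 1
    return CycleDurations(
        durations_s=d,
        mean_s=float(d.mean()),
        sd_s=0.0 if single else float(d.std(ddof=1)),
        single_cycle=single,
    )


def to_cycle_pct(t: float, catch: float, next_catch: float) -> float:
    """Map a sample time onto % of the cycle [catch, next_catch).

    The catch maps to 0% and the next catch to 100%.  Instants within the
    preceding recovery map to negative percentages; instants shortly
    after the next catch (e.g. a silencing that outlasts the cycle) map
    above 100%.  Times more than one full cycle outside are rejected.
    """
    dur = next_catch - catch
    if dur <= 0:
        raise SessionError("next_catch must follow catch")
    pct = 100.0 * (t - catch) / dur
    if not (-100.0 <= pct < 200.0):
        raise SessionError(
            f"time {t} is more than a full cycle outside [{catch}, {next_catch})"
        )
    return pct
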