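"""Domain types, session I/O and validation for rowing surface-EMG trials.

A *session* is one rowing trial: 16 bipolar surface-EMG channels (8 leg
muscles x 2 body sides) sampled at 2048 Hz together with a synchronously
sampled handle-position trace from the ergometer encoder.  A *rest
recording* is a short (>= 5 s) multichannel recording taken while the
rower sits relaxed on the machine; it defines the silence baseline used
by the activity detector.

On disk a session is a directory holding plain-text artifacts:

    session.yaml   sampling rate, units, nominal stroke rate, channel map
    emg.csv        one column per channel, header "muscle_side", uV
    handle.csv     single column "handle_mm"
    rest.yaml      sampling rate and duration of the rest recording
    rest.csv       one column per channel, uV

Samples round-trip bit-exactly (floats are written with 17 significant
digits).  EMG is stored in microvolts and handle position in millimetres;
sample indexing is 0-based and time in seconds is ``index / fs``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

MUSCLES = (
    "tibialis_anterior",
    "gastrocnemius_medialis",
    "soleus",
    "vastus_lateralis",
    "vastus_medialis",
    "rectus_femoris",
    "biceps_femoris",
    "semitendinosus",
)
SIDES = ("left", "right")

#: fraction of samples pinned at a rail value before a clipping finding is raised
CLIP_FRACTION = 1e-3


class SessionError(ValueError):
    """Malformed session data or container."""


@dataclass(frozen=True)
class ChannelMeta:
    """Identity and quality flag of one EMG channel."""

    muscle: str
    side: str
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise SessionError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise SessionError(f"unknown side {self.side!r}")

    @property
    def label(self) -> str:
        return f"{self.muscle}_{self.side}"


def default_montage() -> list[ChannelMeta]:
    """The full 16-channel montage: 8 muscles on both sides."""
    return [ChannelMeta(m, s) for m in MUSCLES for s in SIDES]


@dataclass
class Recording:
    """One trial: multichannel raw EMG plus the handle-position trace.

    ``emg`` has shape (n_channels, n_samples) in uV, ``handle`` has shape
    (n_samples,) in mm and shares the EMG timeline sample-for-sample.
    """

    fs: float
    emg: np.ndarray
    handle: np.ndarray | None
    channels: list[ChannelMeta]
    stroke_rate_nominal: float | None = None

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.handle is not None:
            self.handle = np.asarray(self.handle, dtype=np.float64)
        if self.fs <= 0:
            raise SessionError(f"fs must be positive, got {self.fs}")
        if self.emg.ndim != 2:
            raise SessionError("emg must be a (channels, samples) array")
        if not self.channels:
            raise SessionError("channel list must be non-empty")
        if self.emg.shape[0] != len(self.channels):
            raise SessionError(
                f"{len(self.channels)} channels in metadata but "
                f"{self.emg.shape[0]} rows of samples"
            )
        labels = [c.label for c in self.channels]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise SessionError(f"duplicate (muscle, side) pairs: {sorted(dupes)}")
        if self.handle is not None and self.handle.shape[0] != self.emg.shape[1]:
            raise SessionError(
                f"handle has {self.handle.shape[0]} samples, "
                f"emg has {self.emg.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, muscle: str, side: str) -> int:
        for i, c in enumerate(self.channels):
            if c.muscle == muscle and c.side == side:
                return i
        raise KeyError(f"no channel {muscle}/{side}")


@dataclass
class RestRecording:
    """Relaxed-sitting recording used to estimate the silence baseline."""

    fs: float
    emg: np.ndarray
    duration_s: float
    channels: list[ChannelMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.emg.ndim != 2:
            raise SessionError("rest emg must be a (channels, samples) array")
        expected = self.duration_s * self.fs
        if abs(self.emg.shape[1] - expected) > 1.0:
            raise SessionError(
                f"rest duration {self.duration_s} s at {self.fs} Hz implies "
                f"{expected:.0f} samples, got {self.emg.shape[1]}"
            )


@dataclass(frozen=True)
class Finding:
    """One data-quality observation from validate_recording."""

    channel: str | None
    kind: str  # "flat" | "clipping" | "nan"
    detail: str


def _write_matrix(path: Path, data: np.ndarray, header: list[str]) -> None:
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    np.savetxt(buf, np.atleast_2d(data).T, fmt="%.17g", delimiter=",")
    path.write_text(buf.getvalue())


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return data.T, header


def write_session(
    rec: Recording, path: str | Path, rest: RestRecording | None = None
) -> Path:
    """Write a session container directory; returns its path.

    ``read_session(write_session(rec, p), ...)`` reproduces every sample
    bit-exactly and all metadata.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": float(rec.fs),
        "units": {"emg": "uV", "handle": "mm"},
        "stroke_rate_nominal": (
            None if rec.stroke_rate_nominal is None else float(rec.stroke_rate_nominal)
        ),
        "has_handle": rec.handle is not None,
        "channels": [
            {"muscle": c.muscle, "side": c.side, "excluded": bool(c.excluded)}
            for c in rec.channels
        ],
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    _write_matrix(path / "emg.csv", rec.emg, [c.label for c in rec.channels])
    if rec.handle is not None:
        _write_matrix(path / "handle.csv", rec.handle, ["handle_mm"])
    if rest is not None:
        write_rest(rest, path)
    return path


def write_rest(rest: RestRecording, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": float(rest.fs),
        "duration_s": float(rest.duration_s),
        "channels": [
            {"muscle": c.muscle, "side": c.side, "excluded": bool(c.excluded)}
            for c in rest.channels
        ],
    }
    (path / "rest.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    header = (
        [c.label for c in rest.channels]
        if rest.channels
        else [f"ch{i}" for i in range(rest.emg.shape[0])]
    )
    _write_matrix(path / "rest.csv", rest.emg, header)
    return path


def read_session(path: str | Path, require_handle: bool = True) -> Recording:
    """Read a session container written by :func:`write_session`.

    Raises :class:`SessionError` naming the offending field or channel when
    the container is inconsistent (missing handle trace, channels listed in
    metadata but absent from the sample matrix, length mismatches).
    """
    path = Path(path)
    sidecar = path / "session.yaml"
    if not sidecar.exists():
        raise SessionError(f"no session.yaml in {path}")
    meta = yaml.safe_load(sidecar.read_text())
    channels = [
        ChannelMeta(c["muscle"], c["side"], bool(c.get("excluded", False)))
        for c in meta["channels"]
    ]
    emg, header = _read_matrix(path / "emg.csv")
    missing = [c.label for c in channels if c.label not in header]
    if missing:
        raise SessionError(
            f"channels listed in metadata but missing from emg.csv: {missing}"
        )
    # reorder columns to the metadata channel order
    emg = emg[[header.index(c.label) for c in channels]]
    handle = None
    if (path / "handle.csv").exists():
        handle, _ = _read_matrix(path / "handle.csv")
        handle = handle[0]
    elif meta.get("has_handle") or require_handle:
        raise SessionError(f"missing handle trace (handle.csv) in {path}")
    return Recording(
        fs=float(meta["fs"]),
        emg=emg,
        handle=handle,
        channels=channels,
        stroke_rate_nominal=meta.get("stroke_rate_nominal"),
    )


def read_rest(path: str | Path) -> RestRecording:
    path = Path(path)
    sidecar = path / "rest.yaml"
    if not sidecar.exists():
        raise SessionError(f"no rest.yaml in {path}")
    meta = yaml.safe_load(sidecar.read_text())
    emg, _ = _read_matrix(path / "rest.csv")
    channels = [
        ChannelMeta(c["muscle"], c["side"], bool(c.get("excluded", False)))
        for c in meta.get("channels", [])
    ]
    return RestRecording(
        fs=float(meta["fs"]),
        emg=emg,
        duration_s=float(meta["duration_s"]),
        channels=channels,
    )


def validate_recording(rec: Recording) -> list[Finding]:
    """Screen channels for obvious acquisition problems.

    Pure function (never mutates the recording).  Flags: flat-lined
    channels (sample SD ~ 0), clipping (>= 0.1% of samples pinned at the
    channel's extreme values, as happens when the A/D rails are hit), and
    NaN runs.  This replaces manual visual channel inspection with a
    reproducible screen; excluded channels are still validated.
    """
    findings: list[Finding] = []
    for c, x in zip(rec.channels, rec.emg):
        n = x.size
        n_nan = int(np.isnan(x).sum())
        if n_nan:
            findings.append(Finding(c.label, "nan", f"{n_nan} NaN samples"))
            x = x[~np.isnan(x)]
            if x.size == 0:
                continue
        if np.std(x) < 1e-9:
            findings.append(Finding(c.label, "flat", "sample SD ~ 0"))
            continue
        lo, hi = x.min(), x.max()
        frac_lo = np.mean(x == lo)
        frac_hi = np.mean(x == hi)
        # a continuous signal attains its extremes once; repeated rail values
        # (at least 2, and >= 0.1% of samples) indicate A/D saturation
        if max(frac_lo, frac_hi) >= CLIP_FRACTION and max(
            (x == lo).sum(), (x == hi).sum()
        ) >= 2:
            findings.append(
                Finding(
                    c.label,
                    "clipping",
                    f"{100 * max(frac_lo, frac_hi):.2f}% of samples at a rail value",
                )
            )
    return findings
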