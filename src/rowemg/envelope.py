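"""Surface-EMG envelope extraction.

The envelope chain is the classic linear-envelope estimator: zero-phase
band-pass (20-400 Hz, 2nd-order Butterworth per pass), full-wave
rectification, then a zero-phase 5 Hz low-pass of the same family.  Both
filters are applied forward and backward, so the stated corner frequency
is the -3 dB point of a single pass and the -6 dB point of the combined
two-pass response, and the envelope carries no group delay relative to
the raw signal.

Zero-phase low-passing a rectified signal can ring slightly below zero;
negative envelope samples are clamped to 0 so threshold crossings stay
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class EnvelopeParams:
    """Filter parameters of the envelope chain.

    Corners are the per-pass -3 dB frequencies; with the forward+backward
    application the combined attenuation at each corner is 6 dB.
    """

    bp_low: float = 20.0
    bp_high: float = 400.0
    bp_order: int = 2
    lp_cut: float = 5.0
    lp_order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.bp_low < self.bp_high < fs / 2):
            raise ValueError(
                f"band edges ({self.bp_low}, {self.bp_high}) Hz invalid for fs={fs}"
            )
        if not (0 < self.lp_cut < fs / 2):
            raise ValueError(f"lowpass cut {self.lp_cut} Hz invalid for fs={fs}")


def _filtfilt_reflect(sos: np.ndarray, x: np.ndarray, pad: int) -> np.ndarray:
    """Two-pass filtering with explicit even-reflection padding.

    ``pad`` samples are mirrored at each end before filtering and trimmed
    afterwards, suppressing endpoint transients that would otherwise
    corrupt onsets in the first and last cycles.
    """
    pad = min(pad, x.size - 1)
    if pad > 0:
        x_p = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    else:
        x_p = x
    y = sps.sosfiltfilt(sos, x_p, padlen=0)
    return y[pad : pad + x.size] if pad > 0 else y


def bandpass(x: np.ndarray, fs: float, params: EnvelopeParams | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the raw EMG.

    Requires the input to be several times longer than the filter's
    settling length (~3 periods of the low corner).
    """
    params = params or EnvelopeParams()
    params.validate(fs)
    pad = int(3 * fs / params.bp_low)
    if x.size <= max(pad, 3 * (2 * params.bp_order + 1)):
        raise ValueError(
            f"sequence of {x.size} samples too short for the "
            f"{params.bp_low} Hz band edge at fs={fs}"
        )
    sos = sps.butter(
        params.bp_order, [params.bp_low, params.bp_high], btype="bandpass", fs=fs, output="sos"
    )
    if not params.zero_phase:
        return sps.sosfilt(sos, x)
    return _filtfilt_reflect(sos, x, pad)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(x)


def lowpass(x: np.ndarray, fs: float, params: EnvelopeParams | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass used for envelope smoothing."""
    params = params or EnvelopeParams()
    params.validate(fs)
    sos = sps.butter(params.lp_order, params.lp_cut, btype="low", fs=fs, output="sos")
    if not params.zero_phase:
        return sps.sosfilt(sos, x)
    return _filtfilt_reflect(sos, x, int(3 * fs / params.lp_cut))


def envelope(x: np.ndarray, fs: float, params: EnvelopeParams | None = None) -> np.ndarray:
    """Linear envelope: lowpass(rectify(bandpass(x))), clamped at zero.

    For amplitude-modulated Gaussian noise with slowly varying scale
    sigma(t), the envelope tracks E|N(0, sigma^2)| = sqrt(2/pi) * sigma(t).
    Scale-equivariant: envelope(k*x) == k*envelope(x) for k >= 0.
    """
    params = params or EnvelopeParams()
    env = lowpass(rectify(bandpass(x, fs, params)), fs, params)
    return np.maximum(env, 0.0)
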