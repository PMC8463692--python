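"""Derivation of LFP and ESA continuous signals from broadband recordings.

Two parallel chains, both ending on a common 1 kHz grid:

* LFP: zero-phase 4th-order Butterworth low-pass (100 Hz by default),
  then polyphase resampling to 1 kHz.
* ESA (entire spiking activity): zero-phase 1st-order Butterworth
  high-pass at 300 Hz, full-wave rectification, zero-phase 1st-order
  low-pass at 12 Hz, then resampling to 1 kHz.  ESA is a threshold-less,
  continuous proxy for population spiking around the electrode tip.

All filtering is forward-backward (filtfilt), so the effective magnitude
response is |H(f)|^2 and the net phase is zero.  Channels are processed
independently; no re-referencing is applied.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signals import ContinuousSignal, RawRecording

DERIVED_FS = 1000.0

_BTYPE = {"low": "lowpass", "high": "highpass", "band": "bandpass"}


def zero_phase_filter(
    x: np.ndarray,
    fs: float,
    order: int,
    cutoff: float | tuple[float, float],
    kind: str = "low",
) -> np.ndarray:
    """Forward-backward Butterworth filter along the last axis.

    Edge transients are suppressed by odd-reflection padding covering
    three time constants of the lowest cutoff (at least 3 * (order + 1)
    samples, capped at the signal length).  The two passes square the
    magnitude response and cancel the phase, so in-band components
    emerge with zero lag.

    Raises
    ------
    ValueError
        If any cutoff reaches the Nyquist frequency or ``kind`` is not
        one of ``low``/``high``/``band``.
    """
    if kind not in _BTYPE:
        raise ValueError(f"unknown filter kind {kind!r}")
    if np.max(cutoff) >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, dtype=float)
    low = float(np.min(cutoff))
    padlen = int(min(max(3 * (order + 1), round(3 * fs / low)), x.shape[-1] - 1))
    if x.shape[-1] <= 3 * (order + 1):
        raise ValueError("signal too short for stable forward-backward filtering")
    # second-order sections: transfer-function coefficients are badly
    # conditioned for cutoffs far below Nyquist (e.g. 2 Hz at 1 kHz)
    sos = sps.butter(order, cutoff, btype=_BTYPE[kind], fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def _resample_to_1khz(x: np.ndarray, fs: float) -> np.ndarray:
    """Polyphase resampling to an exact 1 ms grid.

    Handles non-integer ratios (e.g. 24.4 kHz -> 1 kHz is 5/122).  The
    preceding low-pass already provides anti-aliasing; resample_poly's
    own FIR is linear-phase, so the zero-lag contract is preserved.
    """
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"raw sampling rate {fs} Hz must be an integer number of Hz")
    frac = Fraction(1000, int(round(fs)))
    if frac == 1:
        return np.asarray(x, dtype=float)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def extract_lfp(raw: RawRecording, cutoff_hz: float = 100.0) -> ContinuousSignal:
    """Low-pass the raw recording and resample to 1 kHz.

    ``cutoff_hz`` defaults to 100 Hz (guarding the LFP band against
    contamination by multi-unit spike waveforms in 100-300 Hz); 10, 50
    and 300 Hz are the other conventional choices.
    """
    if raw.fs < 2 * cutoff_hz:
        raise ValueError(f"raw fs {raw.fs} Hz too low for a {cutoff_hz} Hz low-pass")
    filtered = zero_phase_filter(raw.signal, raw.fs, order=4, cutoff=cutoff_hz, kind="low")
    out = _resample_to_1khz(filtered, raw.fs)
    return ContinuousSignal(
        kind="lfp",
        fs=DERIVED_FS,
        channel_ids=raw.channel_ids.copy(),
        signal=out,
        provenance=(
            f"butterworth lowpass order=4 cutoff={cutoff_hz}Hz zero-phase "
            "padtype=odd padlen=3/fc",
            f"polyphase resample {raw.fs}Hz->1000Hz",
        ),
    )


def extract_esa(raw: RawRecording) -> ContinuousSignal:
    """High-pass, rectify and smooth the raw recording into ESA at 1 kHz.

    The output may slightly undershoot zero after the 12 Hz low-pass;
    values are deliberately not clipped (tolerated undershoot is checked
    against 5% of the signal RMS by the test suite, not enforced here).
    """
    if raw.fs <= 600:
        raise ValueError(f"raw fs {raw.fs} Hz too low for the 300 Hz ESA high-pass")
    hp = zero_phase_filter(raw.signal, raw.fs, order=1, cutoff=300.0, kind="high")
    rect = np.abs(hp)
    lp = zero_phase_filter(rect, raw.fs, order=1, cutoff=12.0, kind="low")
    out = _resample_to_1khz(lp, raw.fs)
    return ContinuousSignal(
        kind="esa",
        fs=DERIVED_FS,
        channel_ids=raw.channel_ids.copy(),
        signal=out,
        provenance=(
            "butterworth highpass order=1 cutoff=300Hz zero-phase padtype=odd padlen=3/fc",
            "full-wave rectification",
            "butterworth lowpass order=1 cutoff=12Hz zero-phase padtype=odd padlen=3/fc",
            f"polyphase resample {raw.fs}Hz->1000Hz",
        ),
    )
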