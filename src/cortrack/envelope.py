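"""Stimulus amplitude-envelope extraction and conditioning.

The broadband envelope is the magnitude of the analytic signal (Hilbert
transform) of the audio waveform.  Because only the low-frequency envelope
relates linearly to the EEG, the envelope is band-limited to 0.5-15 Hz with
Butterworth filters (6th-order lowpass, 9th-order highpass, applied
zero-phase as second-order sections), RMS-normalized column-wise, and
resampled to the EEG rate.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core import StimulusEnvelope

__all__ = [
    "hilbert_envelope",
    "band_limit",
    "normalize_rms",
    "resample_envelope",
]


def hilbert_envelope(audio: np.ndarray, fs: float, phrase_id: str = "") -> StimulusEnvelope:
    """Pointwise magnitude of the analytic signal of ``audio``."""
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size < 8:
        raise ValueError("waveform too short (need >= 8 samples)")
    if not np.all(np.isfinite(audio)):
        raise ValueError("waveform contains NaN or Inf")
    env = np.abs(sps.hilbert(audio))
    return StimulusEnvelope(samples=env, fs=fs, phrase_id=phrase_id)


def band_limit(
    env: StimulusEnvelope, low: float = 0.5, high: float = 15.0,
    lp_order: int = 6, hp_order: int = 9,
) -> StimulusEnvelope:
    """Band-limit the envelope to ``low``-``high`` Hz.

    Lowpass (order ``lp_order``) then highpass (order ``hp_order``)
    Butterworth filters realized as second-order sections and applied
    forward-backward (zero-phase), which preserves the envelope-EEG temporal
    alignment that lagged decoding relies on.  Removes DC.
    """
    if env.fs <= 30.0:
        raise ValueError("band_limit requires fs > 30 Hz")
    sos_lp = sps.butter(lp_order, high, btype="lowpass", fs=env.fs, output="sos")
    sos_hp = sps.butter(hp_order, low, btype="highpass", fs=env.fs, output="sos")
    x = sps.sosfiltfilt(sos_lp, env.samples)
    x = sps.sosfiltfilt(sos_hp, x)
    return env.with_samples(x)


def normalize_rms(x: np.ndarray) -> np.ndarray:
    """Divide each column (or a 1-D series) by its root-mean-square.

    Raises if any column is all zero, naming the column.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    cols = x[:, None] if squeeze else x
    rms = np.sqrt(np.mean(cols**2, axis=0))
    zero = np.flatnonzero(rms == 0)
    if zero.size:
        raise ValueError(f"cannot RMS-normalize all-zero column(s): {zero.tolist()}")
    out = cols / rms
    return out[:, 0] if squeeze else out


def resample_envelope(env: StimulusEnvelope, target_fs: float) -> StimulusEnvelope:
    """Polyphase downsampling of the envelope to the EEG rate."""
    if target_fs == env.fs:
        return env.with_samples(env.samples.copy())
    if target_fs > env.fs:
        raise ValueError("resample_envelope only downsamples")
    frac = Fraction(target_fs / env.fs).limit_denominator(10_000)
    out = sps.resample_poly(env.samples, frac.numerator, frac.denominator)
    return env.with_samples(out, fs=float(target_fs))
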