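"""Raw-recording conditioning: band filtering, downsampling, bad-channel
handling, average reference and phrase epoching.

Filters follow the convention of zero-phase Hamming-windowed FIR bandpasses
with 2 Hz transition bands and half-amplitude (-6 dB) cutoffs; the filter
order follows the Hamming design rule ``order = 3.3 / (transition/fs)``
rounded up to even, so the kernel has odd length and exact linear phase,
and is applied by centred convolution (group delay compensated).

Band-of-interest presets reproduce the analysis bands: the delta, theta and
alpha signals (0.5-4, 4-8, 8-12 Hz) are acquired with filter cutoffs at
0-5, 3-9 and 7-13 Hz respectively, after a 0.5-45 Hz broadband stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import eval_legendre
from scipy.stats import kurtosis as _kurtosis

from .core import EEGRecording, Epoch, EpochSet

__all__ = [
    "FilterSpec",
    "BAND_FILTERS",
    "design_fir",
    "bandpass",
    "downsample",
    "detect_bad_channels",
    "interpolate_channels",
    "average_reference",
    "epoch",
    "average_repetitions",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR bandpass: Hamming window, -6 dB at the cutoffs.

    ``band_lo = 0`` degenerates to a lowpass; ``band_hi >= fs/2`` to a
    highpass.  ``transition_width`` is the width of each transition band in
    Hz (default 2).
    """

    band_lo: float
    band_hi: float
    transition_width: float = 2.0

    def __post_init__(self) -> None:
        if self.band_lo < 0 or self.band_hi <= self.band_lo:
            raise ValueError("require 0 <= band_lo < band_hi")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")


#: Filter cutoffs used to acquire each analysis band.
BAND_FILTERS: dict[str, FilterSpec] = {
    "broadband": FilterSpec(0.5, 45.0),
    "delta": FilterSpec(0.0, 5.0),
    "theta": FilterSpec(3.0, 9.0),
    "alpha": FilterSpec(7.0, 13.0),
}


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Odd-length linear-phase Hamming FIR kernel for ``spec`` at rate ``fs``."""
    if spec.band_hi >= fs / 2 and spec.band_lo <= 0:
        raise ValueError("band must constrain at least one edge below Nyquist")
    order = math.ceil(3.3 * fs / spec.transition_width)
    if order % 2:
        order += 1
    numtaps = order + 1
    if spec.band_lo <= 0:
        return sps.firwin(numtaps, spec.band_hi, window="hamming", fs=fs)
    if spec.band_hi >= fs / 2:
        return sps.firwin(numtaps, spec.band_lo, window="hamming", pass_zero=False, fs=fs)
    return sps.firwin(
        numtaps, [spec.band_lo, spec.band_hi], window="hamming", pass_zero=False, fs=fs
    )


def bandpass(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Zero-phase band filtering of every channel.

    The linear-phase kernel is applied by centred FFT convolution, so the
    output is delay-free (a filtered pulse correlates maximally with the
    input at lag 0) and the magnitude response is -6 dB at the cutoffs.
    """
    taps = design_fir(spec, rec.fs)
    if rec.n_samples <= 3 * taps.size:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than 3 filter lengths "
            f"({3 * taps.size})"
        )
    out = sps.fftconvolve(rec.data, taps[None, :], mode="same", axes=-1)
    return rec.with_data(
        out, "bandpass", band_lo=spec.band_lo, band_hi=spec.band_hi,
        transition_width=spec.transition_width, numtaps=int(taps.size),
    )


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase resampling to ``target_fs`` (must be below the current rate).

    Spectral content below the new Nyquist that survived prior band filtering
    is preserved; the polyphase anti-alias filter guards the rest.
    """
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current sampling rate")
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return rec.with_data(out, "downsample", fs=float(target_fs), source_fs=rec.fs)


def _channel_scores(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel kurtosis, Gaussian negative log-likelihood, and zero-variance flags."""
    var = data.var(axis=-1)
    degenerate = var <= 0
    with np.errstate(all="ignore"):
        kurt = _kurtosis(data, axis=-1, fisher=True, bias=True)
    mu, sigma = data.mean(), data.std()
    if sigma <= 0:
        nll = np.zeros(data.shape[0])
    else:
        nll = 0.5 * np.log(2 * np.pi * sigma**2) + ((data - mu) ** 2).mean(axis=-1) / (
            2 * sigma**2
        )
    return kurt, nll, degenerate


def _robustless_z(values: np.ndarray) -> np.ndarray:
    good = np.isfinite(values)
    z = np.zeros_like(values, dtype=float)
    if good.sum() < 2:
        return z
    mu = values[good].mean()
    sd = values[good].std()
    if sd > 0:
        z[good] = (values[good] - mu) / sd
    z[~good] = np.inf  # undefined statistic counts as deviant
    return z


def detect_bad_channels(rec: EEGRecording, threshold: float = 3.0) -> np.ndarray:
    """Channels whose kurtosis or Gaussian log-probability deviates > 3 SD.

    Both measures are z-scored across channels (non-robust mean/SD); a
    channel is flagged if either |z| exceeds ``threshold``.  Zero-variance
    channels are always flagged.  Returns channel indices (possibly empty).
    """
    if rec.n_channels < 8:
        raise ValueError("bad-channel detection needs at least 8 channels")
    kurt, nll, degenerate = _channel_scores(rec.data)
    z_k = _robustless_z(kurt)
    z_p = _robustless_z(nll)
    bad = (np.abs(z_k) > threshold) | (np.abs(z_p) > threshold) | degenerate
    return np.flatnonzero(bad)


def _spline_kernel(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos angle): truncated Legendre series."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return g / (4.0 * np.pi)


def interpolate_channels(
    rec: EEGRecording, bad: np.ndarray, m: int = 4, n_terms: int = 7
) -> EEGRecording:
    """Replace ``bad`` channels by spherical-spline estimates from the rest.

    Fits, per time sample, a spherical spline (stiffness ``m``, ``n_terms``
    Legendre terms) to the good channels and evaluates it at the bad sensor
    positions; good channels pass through unchanged.
    """
    bad = np.asarray(bad, dtype=int)
    if bad.size == 0:
        return rec.with_data(rec.data.copy(), "interpolate_channels", bad=[])
    if np.any(bad < 0) or np.any(bad >= rec.n_channels):
        raise ValueError("bad channel index out of range")
    good = np.setdiff1d(np.arange(rec.n_channels), bad)
    if good.size < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos = rec.layout.positions
    g_gg = _spline_kernel(pos[good] @ pos[good].T, m, n_terms)
    g_bg = _spline_kernel(pos[bad] @ pos[good].T, m, n_terms)
    k = good.size
    a = np.zeros((k + 1, k + 1))
    a[:k, :k] = g_gg
    a[:k, k] = 1.0
    a[k, :k] = 1.0
    rhs = np.vstack([rec.data[good], np.zeros(rec.n_samples)])
    sol = np.linalg.lstsq(a, rhs, rcond=None)[0]
    coeffs, const = sol[:k], sol[k]
    out = rec.data.copy()
    out[bad] = const + g_bg @ coeffs
    return rec.with_data(
        out, "interpolate_channels",
        bad=[rec.layout.ids[i] for i in bad], m=m, n_terms=n_terms,
    )


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the across-channel average (a projection: idempotent)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(out, "average_reference")


def epoch(
    rec: EEGRecording,
    annotations: pd.DataFrame,
    interpolate_per_epoch: bool = True,
    threshold: float = 3.0,
) -> EpochSet:
    """Cut phrase-aligned epochs and clean single noisy channels per epoch.

    One epoch per annotation row (phrase_id, repetition).  Within each epoch,
    bad channels are re-detected with the same 3 SD kurtosis/probability rule
    and spherically interpolated; the affected channels are logged per epoch
    in ``interp_log``.
    """
    epochs: list[Epoch] = []
    interp_log: dict[tuple[str, int], list[str]] = {}
    for _, row in annotations.iterrows():
        a = int(round(row["onset_s"] * rec.fs))
        b = int(round(row["offset_s"] * rec.fs))
        if a < 0 or b > rec.n_samples or b <= a:
            raise ValueError(
                f"annotation for phrase {row['phrase_id']!r} (rep {row['repetition']}) "
                "lies outside the recording"
            )
        seg = EEGRecording(rec.data[:, a:b].copy(), rec.fs, rec.layout)
        key = (str(row["phrase_id"]), int(row["repetition"]))
        if interpolate_per_epoch and rec.n_channels >= 8:
            bad = detect_bad_channels(seg, threshold=threshold)
            if bad.size and rec.n_channels - bad.size >= 4:
                seg = interpolate_channels(seg, bad)
                interp_log[key] = [rec.layout.ids[i] for i in bad]
        epochs.append(Epoch(phrase_id=key[0], repetition=key[1], data=seg.data))
    return EpochSet(
        epochs=epochs, fs=rec.fs, layout=rec.layout, interp_log=interp_log,
        meta=rec.meta + [{"op": "epoch", "n_epochs": len(epochs)}],
    )


def average_repetitions(ep: EpochSet) -> EpochSet:
    """Average the repetitions of each phrase into one epoch per phrase.

    Unequal repetition lengths are truncated to the shortest before
    averaging (alignment to phrase onset is preserved); any truncation is
    logged in ``meta``.
    """
    by_phrase: dict[str, list[Epoch]] = {}
    order: list[str] = []
    for e in ep.epochs:
        if e.phrase_id not in by_phrase:
            order.append(e.phrase_id)
        by_phrase.setdefault(e.phrase_id, []).append(e)
    out: list[Epoch] = []
    truncated: list[str] = []
    for pid in order:
        group = by_phrase[pid]
        n_min = min(e.data.shape[1] for e in group)
        if any(e.data.shape[1] != n_min for e in group):
            truncated.append(pid)
        avg = np.mean([e.data[:, :n_min] for e in group], axis=0)
        out.append(Epoch(phrase_id=pid, repetition=0, data=avg))
    return EpochSet(
        epochs=out, fs=ep.fs, layout=ep.layout, interp_log=dict(ep.interp_log),
        meta=ep.meta + [{"op": "average_repetitions", "truncated": truncated}],
    )
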