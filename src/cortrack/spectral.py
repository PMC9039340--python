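"""Periodogram power spectral density and peak screening.

The PSD of each channel is the rectangular-window periodogram

    P(f) = (dt / N) |sum_n x_n exp(-j 2 pi f dt n)|^2

with one-sided scaling: every bin except DC and Nyquist is doubled to
conserve total power.  Zero-padding to a common DFT length refines the
frequency grid across subjects without changing the normalization, which
always uses the original sample count N.  Peak values are read as the
maximum channel-averaged power inside a 1 Hz window around a centre
frequency, and per-subject peak lists are screened with the 1.5 IQR
quartile rule before group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EEGRecording, EpochSet

__all__ = [
    "PSDEstimate",
    "periodogram_psd",
    "concatenate_epochs",
    "peak_power",
    "peak_table",
    "quartile_outliers",
]


@dataclass
class PSDEstimate:
    """One-sided periodogram per channel, power in uV^2/Hz."""

    freqs: np.ndarray  # Hz, 0 .. fs/2
    power: np.ndarray  # (n_channels, n_freqs)
    nfft: int
    fs: float
    condition: str = ""

    @property
    def mean_power(self) -> np.ndarray:
        """Channel-averaged power."""
        return self.power.mean(axis=0)


def periodogram_psd(
    rec: EEGRecording, nfft: int | None = None, condition: str = ""
) -> PSDEstimate:
    """One-sided rectangular-window periodogram of every channel.

    ``nfft`` zero-pads the DFT (it must be at least the sample count; no
    truncation).  The normalization dt/N uses the original sample count
    regardless of padding, and all bins except 0 and Nyquist are doubled.
    """
    n = rec.n_samples
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(n)))
    if nfft < n:
        raise ValueError("nfft must be >= the sample count (no truncation)")
    freqs, power = sps.periodogram(
        rec.data, fs=rec.fs, window="boxcar", nfft=nfft,
        detrend=False, scaling="density", axis=-1,
    )
    return PSDEstimate(freqs=freqs, power=power, nfft=int(nfft), fs=rec.fs, condition=condition)


def concatenate_epochs(ep: EpochSet) -> EEGRecording:
    """Concatenate epochs (in presentation order) into one continuous signal."""
    if not ep.epochs:
        raise ValueError("no epochs to concatenate")
    n_ch = ep.epochs[0].data.shape[0]
    if any(e.data.shape[0] != n_ch for e in ep.epochs):
        raise ValueError("inconsistent channel counts across epochs")
    data = np.concatenate([e.data for e in ep.epochs], axis=-1)
    return EEGRecording(
        data=data, fs=ep.fs, layout=ep.layout,
        meta=ep.meta + [{"op": "concatenate_epochs", "n_epochs": len(ep.epochs)}],
    )


def peak_power(psd: PSDEstimate, center: float, width: float = 1.0) -> float:
    """Maximum channel-averaged power within ``center`` +/- ``width``/2 Hz."""
    lo, hi = center - width / 2.0, center + width / 2.0
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(f"window [{lo}, {hi}] Hz outside the frequency range")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not mask.any():
        raise ValueError("empty frequency window")
    return float(psd.mean_power[mask].max())


def peak_table(
    psd: PSDEstimate,
    centers: tuple[float, ...] = (1.25, 8.54, 10.04),
    width: float = 1.0,
    subject: str = "",
) -> pd.DataFrame:
    """Peak power per centre frequency as a tidy table."""
    rows = [
        {
            "subject": subject,
            "condition": psd.condition,
            "center_freq": c,
            "window_width": width,
            "peak_power": peak_power(psd, c, width),
        }
        for c in centers
    ]
    return pd.DataFrame(rows)


def quartile_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1.5 IQR rule with midpoint-interpolated quartiles.

    Returns ``(kept_idx, flagged_idx)``: values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartile screening")
    q1, q3 = np.percentile(values, [25, 75], method="midpoint")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = (values < lo) | (values > hi)
    return np.flatnonzero(~flagged), np.flatnonzero(flagged)
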