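"""Phase-amplitude coupling via the normalized modulation index (nMI).

Coupling between a low-frequency phase (LFP) and a high-frequency amplitude
(HFA) is quantified with the mean-vector modulation index

    MI = | mean( A(t) * exp(i * phi(t)) ) |

where phi is the angle and A the magnitude of the analytic signals of the
band-filtered data.  LFP centre frequencies run 2-8 Hz in 1 Hz steps with a
2 Hz-wide band; HFA centres run 17.5-42.5 Hz in 5 Hz steps with bands of
+/-5 Hz around each centre; both use zero-phase Hamming-window FIR
filters.  The amplitude bands are wider than the 5 Hz centre spacing on
purpose: a sub-band envelope cannot fluctuate faster than the band width,
so amplitude bandwidth must be at least twice the fastest phase frequency
of interest for phase-amplitude coupling in the theta range to be
measurable at all.  The MI is
computed in sliding 5 s windows with 2.5 s overlap and normalized against
200 surrogates built by circularly rotating the amplitude series:

    nMI = (MI - surrogate mean) / surrogate SD.

Windows are significant if they exceed the one-sided 95 % Gaussian bound of
their surrogates and survive family-wise error correction across the
windows of the cell (max-statistic permutation correction by default, Holm
available); surviving windows are averaged per (channel, LFP, HFA) cell,
and the strongest channel within each delta/theta x beta/gamma grouping is
the subject-level result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .core import EEGRecording
from .preprocess import FilterSpec, design_fir

__all__ = [
    "PACGrid",
    "BandGroupResult",
    "PHASE_CENTERS",
    "AMP_CENTERS",
    "BAND_GROUPS",
    "extract_phase_amp",
    "canolty_mi",
    "surrogate_mis",
    "nmi",
    "sliding_windows",
    "significant_windows",
    "compute_pac_grid",
    "aggregate_cells",
    "band_group_max",
]

PHASE_CENTERS: tuple[float, ...] = tuple(float(f) for f in range(2, 9))
AMP_CENTERS: tuple[float, ...] = tuple(17.5 + 5.0 * k for k in range(6))

#: Band groupings by centre frequency.  The shared 4 Hz edge goes to theta;
#: the 30 Hz amplitude edge goes to gamma (centres, not band edges, decide).
BAND_GROUPS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "delta/beta": ((2.0, 4.0), (15.0, 30.0)),
    "delta/gamma": ((2.0, 4.0), (30.0, 45.0)),
    "theta/beta": ((4.0, 8.0), (15.0, 30.0)),
    "theta/gamma": ((4.0, 8.0), (30.0, 45.0)),
}


@dataclass
class BandGroupResult:
    """Strongest channel and nMI within one phase x amplitude grouping."""

    grouping: str
    best_channel: str | None
    best_nmi: float  # NaN when no cell in the grouping has significant windows


@dataclass
class PACGrid:
    """Per-channel nMI results over the (phase-centre, amplitude-centre) grid.

    ``cells`` is a long-format table with one row per
    (channel, phase_center, amp_center): number of windows, number of
    significant windows, and the mean nMI over significant windows (NaN if
    none survive).
    """

    cells: pd.DataFrame
    fs: float
    window_len: float = 5.0
    overlap: float = 2.5
    n_surrogates: int = 200
    phase_bw: float = 2.0
    amp_bw: float = 10.0
    meta: dict = field(default_factory=dict)


def _band_filter(x: np.ndarray, fs: float, center: float, bw: float,
                 transition: float | None = None) -> np.ndarray:
    """Zero-phase Hamming FIR bandpass around ``center`` +/- ``bw``/2.

    The transition width follows the same 2 Hz convention as the broadband
    preprocessing filters, shrunk for bands whose lower edge sits below 2 Hz.
    """
    lo, hi = center - bw / 2.0, center + bw / 2.0
    if hi >= fs / 2.0:
        raise ValueError(f"band {lo}-{hi} Hz reaches Nyquist ({fs / 2} Hz)")
    if transition is None:
        transition = min(2.0, max(0.5, lo))
    taps = design_fir(FilterSpec(lo, hi, transition_width=transition), fs)
    return sps.fftconvolve(np.atleast_2d(x), taps[None, :], mode="same", axes=-1)


def extract_phase_amp(
    rec: EEGRecording | np.ndarray,
    phase_center: float,
    amp_center: float,
    fs: float | None = None,
    phase_bw: float = 2.0,
    amp_bw: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-frequency phase and high-frequency amplitude time series.

    Phase is the angle and amplitude the magnitude of the analytic signal of
    the respective band-filtered data.  Accepts a recording (all channels) or
    a plain array with ``fs``.
    """
    if isinstance(rec, EEGRecording):
        data, fs = rec.data, rec.fs
    else:
        if fs is None:
            raise ValueError("fs required for a plain array")
        data = np.atleast_2d(np.asarray(rec, dtype=float))
    phase = np.angle(sps.hilbert(_band_filter(data, fs, phase_center, phase_bw), axis=-1))
    amp = np.abs(sps.hilbert(_band_filter(data, fs, amp_center, amp_bw), axis=-1))
    if isinstance(rec, np.ndarray) and rec.ndim == 1:
        return phase[0], amp[0]
    return phase, amp


def canolty_mi(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Mean-vector modulation index |mean(A exp(i phi))|."""
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise ValueError("phase and amplitude must have equal length")
    if phase.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(amplitude * np.exp(1j * phase))))


def _all_rotation_mis(phase: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """MI(phase, roll(amplitude, k)) for every offset k, via circular correlation."""
    n = phase.size
    z = np.exp(1j * phase)
    c = np.fft.ifft(np.fft.fft(z) * np.conj(np.fft.fft(amplitude.astype(complex))))
    return np.abs(c) / n


def surrogate_mis(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = 200,
    seed: int | np.random.Generator = 0,
    min_shift: int | None = None,
) -> np.ndarray:
    """Surrogate MIs from circular rotations of the amplitude series.

    Offsets are uniform on [min_shift, n - min_shift) so near-identity
    rotations are excluded; ``min_shift`` defaults to a fifth of the window
    (1 s for the standard 5 s analysis window).
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    n = phase.size
    if min_shift is None:
        min_shift = max(1, n // 5)
    if 2 * min_shift >= n:
        raise ValueError("min_shift too large for the series length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    mi_all = _all_rotation_mis(phase, amplitude)
    return mi_all[offsets]


def nmi(real_mi: float, surrogates: np.ndarray) -> float:
    """z-score of the real MI against the Gaussian fit of its surrogates."""
    surrogates = np.asarray(surrogates, dtype=float)
    sd = surrogates.std()
    if sd <= 0:
        raise ValueError("surrogate SD is zero; nMI undefined")
    return float((real_mi - surrogates.mean()) / sd)


def sliding_windows(
    length: int, fs: float, window: float = 5.0, overlap: float = 2.5
) -> list[tuple[int, int]]:
    """Start/stop sample indices of sliding analysis windows.

    Starts at 0 with step ``window - overlap``; any tail shorter than a full
    window is dropped.  Returns an empty list (with a warning) if the data
    are shorter than one window.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window")
    win_n = int(round(window * fs))
    step = window - overlap
    if length < win_n:
        warnings.warn("data shorter than one analysis window; no windows")
        return []
    out = []
    k = 0
    while True:
        start = int(round(k * step * fs))
        if start + win_n > length:
            break
        out.append((start, start + win_n))
        k += 1
    return out


def _holm_keep(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Holm-Bonferroni step-down; True for rejected (significant) hypotheses."""
    m = pvals.size
    order = np.argsort(pvals)
    keep = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            keep[idx] = True
        else:
            break
    return keep


def significant_windows(
    real_mis: np.ndarray,
    surrogate_means: np.ndarray,
    surrogate_sds: np.ndarray,
    alpha: float = 0.05,
    surrogate_mi_matrix: np.ndarray | None = None,
    method: str = "maxstat",
) -> tuple[np.ndarray, np.ndarray]:
    """Select windows whose MI beats the surrogate 95 % bound, FWE-corrected.

    Every window must first exceed the one-sided ``1 - alpha`` Gaussian
    quantile of its own surrogates (the per-window 95 % confidence bound).
    Family-wise error across the cell's windows is then controlled by one of
    two procedures:

    ``"maxstat"`` (default, requires ``surrogate_mi_matrix`` of shape
    (n_windows, n_surrogates)): each surrogate iteration's MIs are z-scored
    with the same per-window surrogate mean/SD, the maximum surrogate nMI
    across windows is taken per iteration, and a window is kept if its real
    nMI exceeds the ``1 - alpha`` quantile of that maximum distribution.
    This controls FWE exactly under exchangeability, whatever the shape of
    the MI null (which is Rayleigh-like, so Gaussian tail extrapolation
    far beyond the 95 % point is unreliable).

    ``"holm"``: Holm-Bonferroni step-down on the Gaussian one-sided
    p-values of the window nMIs.  Simpler, but inherits the Gaussian tail
    approximation at very small p.

    Returns ``(kept_mask, window_nmis)``.
    """
    real_mis = np.asarray(real_mis, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nmis = (real_mis - surrogate_means) / surrogate_sds
    nmis = np.where(np.isfinite(nmis), nmis, 0.0)
    crit = norm.ppf(1.0 - alpha)
    if method == "maxstat":
        if surrogate_mi_matrix is None:
            raise ValueError("maxstat correction needs the surrogate MI matrix")
        # leave-one-out studentization: the real MI is normalized by moments
        # external to it, so each surrogate must be normalized by the moments
        # of the OTHER surrogates -- self-inclusion would shrink the
        # surrogate maxima and anticonservatively favour the real statistic
        m = surrogate_mi_matrix
        n_s = m.shape[1]
        s1 = m.sum(axis=1, keepdims=True)
        s2 = (m**2).sum(axis=1, keepdims=True)
        loo_mean = (s1 - m) / (n_s - 1)
        loo_var = (s2 - m**2) / (n_s - 1) - loo_mean**2
        with np.errstate(invalid="ignore", divide="ignore"):
            sur_nmis = (m - loo_mean) / np.sqrt(np.maximum(loo_var, 0.0))
        sur_nmis = np.where(np.isfinite(sur_nmis), sur_nmis, 0.0)
        max_null = sur_nmis.max(axis=0)  # per-iteration max across windows
        # exact permutation p: (1 + #{max null >= observed}) / (n + 1)
        n_sur = max_null.size
        exceed = (max_null[None, :] >= nmis[:, None]).sum(axis=1)
        p_fwe = (1.0 + exceed) / (n_sur + 1.0)
        kept = (nmis > crit) & (p_fwe <= alpha)
    elif method == "holm":
        pvals = norm.sf(nmis)
        kept = (nmis > crit) & _holm_keep(pvals, alpha)
    else:
        raise ValueError(f"unknown FWE method: {method!r}")
    return kept, nmis


def compute_pac_grid(
    rec: EEGRecording,
    phase_centers: tuple[float, ...] = PHASE_CENTERS,
    amp_centers: tuple[float, ...] = AMP_CENTERS,
    phase_bw: float = 2.0,
    amp_bw: float = 10.0,
    window: float = 5.0,
    overlap: float = 2.5,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    min_shift_s: float = 1.0,
    fwe_method: str = "maxstat",
) -> PACGrid:
    """Full comodulogram: nMI per (channel, phase-centre, amplitude-centre).

    Filters each channel once per centre frequency and slides the analysis
    window.  Surrogates circularly rotate the channel's full amplitude time
    series (200 iterations, offsets of at least ``min_shift_s``), and every
    window's MI is re-evaluated under each rotation: each window is thus
    compared against amplitude stretches drawn from the whole recording,
    which gives the Gaussian surrogate fit far more independent material
    than rotations confined to one 5 s window would.  Significant windows
    are aggregated per cell.
    """
    fs = rec.fs
    # trim the filters' edge transients plus a guard for the FFT Hilbert
    # transform's slowly decaying (~1/t) edge ringing: the ringing is shared
    # between the phase and amplitude series of a channel and correlates
    # their aligned (real) windows near the edges, which rotation destroys
    # -- left in place it inflates the family-wise error
    lo_edge = min(pc - phase_bw / 2.0 for pc in phase_centers)
    taps_len = design_fir(
        FilterSpec(lo_edge, lo_edge + phase_bw, min(2.0, max(0.5, lo_edge))), fs
    ).size
    trim = taps_len // 2 + int(round(1.5 * fs))
    n = rec.n_samples - 2 * trim
    if n <= 0:
        raise ValueError("recording shorter than the filter edge transients")
    wins = sliding_windows(n, fs, window, overlap)
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * fs))
    if 2 * min_shift >= n:
        raise ValueError("recording too short for the minimum surrogate rotation")
    rows = []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        phases = {
            pc: np.angle(sps.hilbert(_band_filter(x, fs, pc, phase_bw)[0]))[trim:-trim]
            for pc in phase_centers
        }
        amps = {
            ac: np.abs(sps.hilbert(_band_filter(x, fs, ac, amp_bw)[0]))[trim:-trim]
            for ac in amp_centers
        }
        starts = np.array([a for a, _ in wins])
        stops = np.array([b for _, b in wins])
        win_n = stops - starts
        for pc in phase_centers:
            for ac in amp_centers:
                # evenly spaced rotations with a seeded common start: every
                # pair of offsets (and offset 0, the real alignment) is at
                # least min_shift apart, so the real and surrogate columns
                # are jointly exchangeable under the null -- clustered
                # random offsets would create near-duplicate surrogates and
                # inflate the family-wise error
                span = n - 2 * min_shift
                spacing = span / n_surrogates
                if spacing < min_shift:
                    warnings.warn(
                        "surrogate rotations closer than min_shift; "
                        "consider fewer surrogates or a longer recording"
                    )
                start = rng.uniform(0.0, spacing)
                offsets = (min_shift + (start + spacing * np.arange(n_surrogates))).astype(int)
                z = np.exp(1j * phases[pc])
                am = amps[ac]
                # windowed complex means via one cumulative sum per rotation
                cs = np.concatenate([[0.0 + 0.0j], np.cumsum(am * z)])
                real = np.abs(cs[stops] - cs[starts]) / win_n
                sur = np.empty((len(wins), n_surrogates))
                for s, k in enumerate(offsets):
                    cs = np.concatenate([[0.0 + 0.0j], np.cumsum(np.roll(am, k) * z)])
                    sur[:, s] = np.abs(cs[stops] - cs[starts]) / win_n
                    # the roll's wrap seam (at rolled index k) breaks the
                    # amplitude's autocorrelation inside any window covering
                    # it, stochastically lowering that window's surrogate MI
                    # and hence the column maximum; re-evaluate those windows
                    # on a contiguous segment at a shifted offset so real and
                    # surrogate columns stay exchangeable
                    for w in np.flatnonzero((starts < k) & (k < stops)):
                        a, b = int(starts[w]), int(stops[w])
                        wl = b - a
                        k2 = k - wl if k - wl >= min_shift + wl else k + wl
                        s0 = (a - k2) % n
                        seg = am[s0 : s0 + wl]
                        if seg.size == wl:
                            sur[w, s] = np.abs(np.mean(seg * z[a:b]))
                smean = sur.mean(axis=1)
                ssd = sur.std(axis=1)
                kept, nmis = significant_windows(
                    real, smean, ssd, alpha,
                    surrogate_mi_matrix=sur, method=fwe_method,
                )
                rows.append(
                    {
                        "channel": rec.layout.ids[ch],
                        "phase_center": pc,
                        "amp_center": ac,
                        "n_windows": len(wins),
                        "n_sig_windows": int(kept.sum()),
                        "mean_nmi": float(nmis[kept].mean()) if kept.any() else np.nan,
                    }
                )
    cells = pd.DataFrame(rows)
    return PACGrid(
        cells=cells, fs=fs, window_len=window, overlap=overlap,
        n_surrogates=n_surrogates, phase_bw=phase_bw, amp_bw=amp_bw,
        meta={"seed": seed, "alpha": alpha},
    )


def aggregate_cells(grid: PACGrid) -> pd.DataFrame:
    """Per-cell mean nMI over significant windows (already computed per cell)."""
    return grid.cells[
        ["channel", "phase_center", "amp_center", "n_sig_windows", "mean_nmi"]
    ].copy()


def band_group_max(grid: PACGrid) -> list[BandGroupResult]:
    """Strongest (channel, cell) nMI within each predefined band grouping.

    Delta phase centres are in [2, 4) Hz and theta in [4, 8]; beta amplitude
    centres in [15, 30) Hz and gamma in [30, 45].  Groupings where no cell
    has any significant window are flagged with NaN.
    """
    results = []
    for name, ((p_lo, p_hi), (a_lo, a_hi)) in BAND_GROUPS.items():
        if p_hi < 8.0:  # delta: half-open at the shared 4 Hz edge
            p_mask = (grid.cells["phase_center"] >= p_lo) & (grid.cells["phase_center"] < p_hi)
        else:
            p_mask = (grid.cells["phase_center"] >= p_lo) & (grid.cells["phase_center"] <= p_hi)
        if a_hi < 45.0:  # beta: half-open at the shared 30 Hz edge
            a_mask = (grid.cells["amp_center"] >= a_lo) & (grid.cells["amp_center"] < a_hi)
        else:
            a_mask = (grid.cells["amp_center"] >= a_lo) & (grid.cells["amp_center"] <= a_hi)
        sub = grid.cells[p_mask & a_mask]
        if sub.empty or sub["mean_nmi"].isna().all():
            results.append(BandGroupResult(grouping=name, best_channel=None, best_nmi=float("nan")))
            continue
        best = sub.loc[sub["mean_nmi"].idxmax()]
        results.append(
            BandGroupResult(
                grouping=name,
                best_channel=str(best["channel"]),
                best_nmi=float(best["mean_nmi"]),
            )
        )
    return results
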