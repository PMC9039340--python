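"""Backward TRF stimulus reconstruction.

A linear decoder g(tau, n) maps the multichannel neural response r(t, n) at
lags tau in [0, 250] ms back to the stimulus envelope s(t):

    s_hat(t) = sum_n sum_tau r(t + tau, n) g(tau, n)

Decoders are trained by ridge regression, (X'X + lambda I) w = X's, with the
penalty chosen on a 12-point log grid (1e-3 .. 1e8) by leave-one-out
cross-validation: per fold, one decoder is trained per training trial, the
weight matrices are averaged, the held-out trial is reconstructed, and the
reconstruction is scored with Pearson's r.  The selected lambda is the
smallest on the grid whose mean r is within a small tolerance of the best.

Both EEG epochs and envelopes are RMS-normalized per column before fitting,
which keeps the lambda search range meaningful and removes the need for an
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .core import EpochSet, StimulusEnvelope
from .envelope import normalize_rms

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "DecoderModel",
    "CVResult",
    "make_lags",
    "lag_matrix",
    "ridge_train",
    "reconstruct",
    "pearson_r",
    "select_lambda",
    "cross_validate",
    "prepare_trials",
    "evaluate_cv",
    "forward_lag_profile",
]

#: 12 ridge penalties, log-spaced 1e-3 .. 1e8.
DEFAULT_LAMBDA_GRID: np.ndarray = 10.0 ** np.arange(-3, 9).astype(float)


@dataclass
class DecoderModel:
    """Backward decoder weights g(tau, n) on a lag grid with its penalty."""

    weights: np.ndarray  # (n_lags, n_channels)
    lags: np.ndarray  # lag offsets in samples (non-negative for a causal decoder)
    fs: float
    lam: float

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def flat_weights(self) -> np.ndarray:
        # channel-major, lag-minor: column ch * n_lags + lag
        return self.weights.T.ravel()


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome over the lambda grid."""

    per_trial_r: np.ndarray  # held-out r per trial at the chosen lambda
    mean_r: float
    lambda_grid: np.ndarray
    lambda_curve: np.ndarray  # mean held-out r per lambda
    chosen_lambda: float


def make_lags(fs: float, tau_min: float = 0.0, tau_max: float = 0.25) -> np.ndarray:
    """Integer sample lags floor(tau_min*fs) .. floor(tau_max*fs) inclusive."""
    lo = int(np.floor(tau_min * fs))
    hi = int(np.floor(tau_max * fs))
    return np.arange(lo, hi + 1)


def lag_matrix(data: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time-lagged design matrix; row t holds r(t + tau, n) for all (tau, n).

    Out-of-range lags are zero-padded.  Column order is channel-major,
    lag-minor: column ``ch * n_lags + lag_index``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lags = np.asarray(lags, dtype=int)
    n_ch, n = data.shape
    n_lags = lags.size
    if n <= n_lags:
        raise ValueError("epoch must be longer than the lag count")
    x = np.zeros((n, n_ch * n_lags))
    for li, tau in enumerate(lags):
        if tau >= 0:
            x[: n - tau, li::n_lags] = data[:, tau:].T
        else:
            x[-tau:, li::n_lags] = data[:, : n + tau].T
    return x


def ridge_train(
    design: np.ndarray,
    target: np.ndarray,
    lam: float,
    lags: np.ndarray | None = None,
    fs: float = 1.0,
) -> DecoderModel:
    """Solve the ridge-penalized least squares (X'X + lambda I) w = X's."""
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    if design.shape[0] != target.size:
        raise ValueError("design rows must match target length")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    d = design.shape[1]
    gram = design.T @ design + lam * np.eye(d)
    rhs = design.T @ target
    try:
        w = sla.solve(gram, rhs, assume_a="pos")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular ridge system; use lambda > 0"
        ) from err
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular ridge system; use lambda > 0")
    if lags is None:
        n_lags = 1 if d == 1 else d
        lags = np.arange(n_lags)
    lags = np.asarray(lags, dtype=int)
    weights = w.reshape(-1, lags.size).T  # (n_lags, n_channels)
    return DecoderModel(weights=weights, lags=lags, fs=fs, lam=float(lam))


def reconstruct(model: DecoderModel, epoch_data: np.ndarray) -> np.ndarray:
    """Apply the decoder: s_hat(t) = sum_n sum_tau r(t+tau, n) g(tau, n)."""
    epoch_data = np.atleast_2d(np.asarray(epoch_data, dtype=float))
    if epoch_data.shape[0] != model.n_channels:
        raise ValueError(
            f"epoch has {epoch_data.shape[0]} channels, model expects {model.n_channels}"
        )
    x = lag_matrix(epoch_data, model.lags)
    return x @ model.flat_weights


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length, non-constant series."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for constant input")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def select_lambda(
    lambda_grid: np.ndarray, lambda_curve: np.ndarray, eps: float = 1e-4
) -> float:
    """Smallest lambda whose mean r is within ``eps`` of the grid maximum."""
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    lambda_curve = np.asarray(lambda_curve, dtype=float)
    best = lambda_curve.max()
    idx = int(np.flatnonzero(lambda_curve >= best - eps)[0])
    return float(lambda_grid[idx])


@dataclass
class _TrialDesign:
    """Precomputed per-trial quantities reused across lambdas and permutations."""

    x: np.ndarray  # (n, d) lagged design
    target: np.ndarray  # (n,) normalized envelope
    evals: np.ndarray  # eigenvalues of X'X
    q: np.ndarray  # eigenvectors of X'X
    qt_xt: np.ndarray  # Q' X'  (d, n): maps a target to Q' X's


def prepare_trials(
    epochs: EpochSet | list[np.ndarray],
    envelopes: list[StimulusEnvelope] | list[np.ndarray],
    tau_min: float = 0.0,
    tau_max: float = 0.25,
    fs: float | None = None,
    normalize: bool = True,
) -> tuple[list[_TrialDesign], np.ndarray, float]:
    """Pair and normalize trials, build lag designs, eigendecompose X'X.

    The eigendecomposition makes training at every lambda on the grid (and on
    every permuted envelope) a cheap reuse of the same factorization.
    """
    if isinstance(epochs, EpochSet):
        fs = epochs.fs
        trial_data = [e.data for e in epochs.epochs]
        ids = [e.phrase_id for e in epochs.epochs]
        env_by_id = {env.phrase_id: env for env in envelopes}
        if set(ids) <= set(env_by_id):
            envelopes = [env_by_id[i] for i in ids]
    else:
        if fs is None:
            raise ValueError("fs required when epochs is a plain list")
        trial_data = [np.atleast_2d(np.asarray(e, dtype=float)) for e in epochs]
    if len(trial_data) != len(envelopes):
        raise ValueError("need one envelope per epoch")
    lags = make_lags(fs, tau_min, tau_max)
    designs: list[_TrialDesign] = []
    for data, env in zip(trial_data, envelopes):
        s = env.samples if isinstance(env, StimulusEnvelope) else np.asarray(env, dtype=float)
        if s.size != data.shape[1]:
            raise ValueError("epoch/envelope length mismatch within a pair")
        if normalize:
            data = normalize_rms(data.T).T
            s = normalize_rms(s)
        x = lag_matrix(data, lags)
        gram = x.T @ x
        evals, q = np.linalg.eigh(gram)
        evals = np.maximum(evals, 0.0)
        designs.append(_TrialDesign(x=x, target=s, evals=evals, q=q, qt_xt=q.T @ x.T))
    return designs, lags, float(fs)


def evaluate_cv(
    designs: list[_TrialDesign],
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    targets: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-lambda, per-fold held-out reconstruction r; shape (n_lambda, M).

    ``targets`` overrides the stored envelopes (used by the permutation
    null, which re-decodes permuted envelopes against unchanged EEG).
    """
    m = len(designs)
    if m < 3:
        raise ValueError("cross-validation needs at least 3 trials")
    grid = np.asarray(lambda_grid, dtype=float)
    d = designs[0].q.shape[0]
    n_lam = grid.size
    w = np.empty((m, d, n_lam))
    for j, td in enumerate(designs):
        s = td.target if targets is None else np.asarray(targets[j], dtype=float)
        b = td.qt_xt @ s  # Q' X' s
        w[j] = td.q @ (b[:, None] / (td.evals[:, None] + grid[None, :]))
    w_sum = w.sum(axis=0)
    r = np.empty((n_lam, m))
    for f, td in enumerate(designs):
        w_avg = (w_sum - w[f]) / (m - 1)
        s_hat = td.x @ w_avg  # (n_f, n_lam)
        s = td.target if targets is None else np.asarray(targets[f], dtype=float)
        sc = s - s.mean()
        hc = s_hat - s_hat.mean(axis=0)
        denom = np.sqrt((sc**2).sum()) * np.sqrt((hc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, f] = np.where(denom > 0, (hc * sc[:, None]).sum(axis=0) / denom, 0.0)
    return r


def cross_validate(
    epochs: EpochSet | list[np.ndarray],
    envelopes: list[StimulusEnvelope] | list[np.ndarray],
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    tau_min: float = 0.0,
    tau_max: float = 0.25,
    fs: float | None = None,
    eps: float = 1e-4,
) -> CVResult:
    """Leave-one-out decoding of every trial over the lambda grid.

    Per fold, one decoder per training trial is trained and the weight
    matrices averaged; the average model reconstructs the held-out trial and
    is scored with Pearson's r.  The mean over folds per lambda forms the
    lambda curve from which the smallest near-optimal penalty is selected.
    """
    designs, _, _ = prepare_trials(epochs, envelopes, tau_min, tau_max, fs)
    grid = np.asarray(lambda_grid, dtype=float)
    r = evaluate_cv(designs, grid)
    curve = r.mean(axis=1)
    chosen = select_lambda(grid, curve, eps)
    idx = int(np.flatnonzero(grid == chosen)[0])
    return CVResult(
        per_trial_r=r[idx],
        mean_r=float(curve[idx]),
        lambda_grid=grid,
        lambda_curve=curve,
        chosen_lambda=chosen,
    )


def forward_lag_profile(
    epochs: EpochSet | list[np.ndarray],
    envelopes: list[StimulusEnvelope] | list[np.ndarray],
    tau_min: float = 0.0,
    tau_max: float = 0.25,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward (encoding) refit: envelope -> EEG kernel lag profile.

    Fits, by least squares over all trials jointly, the causal forward kernel
    that predicts each channel from the lagged envelope, and returns
    ``(lag_seconds, profile)`` where the profile is the RMS kernel weight
    across channels per lag.  On synthetic tracking data the profile peaks at
    the planted forward-kernel peak, which validates the lag convention of
    the backward decoder end to end.
    """
    if isinstance(epochs, EpochSet):
        fs = epochs.fs
        trial_data = [e.data for e in epochs.epochs]
        env_by_id = {env.phrase_id: env for env in envelopes}
        ids = [e.phrase_id for e in epochs.epochs]
        if set(ids) <= set(env_by_id):
            envelopes = [env_by_id[i] for i in ids]
    else:
        if fs is None:
            raise ValueError("fs required when epochs is a plain list")
        trial_data = [np.atleast_2d(np.asarray(e, dtype=float)) for e in epochs]
    lags = make_lags(fs, tau_min, tau_max)
    xs, ys = [], []
    for data, env in zip(trial_data, envelopes):
        s = env.samples if isinstance(env, StimulusEnvelope) else np.asarray(env, dtype=float)
        s = normalize_rms(s - s.mean())
        # the EEG at time t depends on the envelope at t - tau: negate lags
        xs.append(lag_matrix(s[None, :], -lags[::-1]))
        ys.append(normalize_rms(data.T))
    x = np.vstack(xs)
    y = np.vstack(ys)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)  # (n_lags, n_channels)
    coef = coef[::-1]  # undo lag reversal: row i <-> lag lags[i]
    profile = np.sqrt((coef**2).mean(axis=1))
    return lags / fs, profile
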