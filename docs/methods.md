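# Methods

This note documents the models and procedures implemented in `cortrack`,
the assumptions behind the synthetic-data generator, the numerical choices
made where the design was genuinely open, and the known limitations of
what passing tests establish.

## Backward TRF stimulus reconstruction (`decode`)

The decoder is the standard backward multivariate temporal response
function: ŝ(t) = Σ_n Σ_τ r(t+τ, n) g(τ, n) with integer sample lags from
floor(τ_min·fs) to floor(τ_max·fs) (τ_min = 0, τ_max = 0.25 s; 26 lags at
100 Hz). The design matrix is zero-padded at epoch edges so reconstructions
have trial length. Weights solve (XᵀX + λI)w = Xᵀs.

*Cross-validation.* Leave-one-out over phrase trials: per fold, one decoder
per training trial is trained and the weight matrices averaged (model
averaging, not prediction averaging); the average model reconstructs the
held-out trial, scored by Pearson r. This repeats over the λ grid
{10⁻³ … 10⁸} (12 log-spaced values). The selected λ is the smallest whose
mean r is within ε = 1e-4 of the grid maximum — a small ε deliberately
favours less regularization. EEG channels and envelopes are both
RMS-normalized per column before fitting, so no intercept is needed and the
λ grid spans a meaningful range.

*Implementation.* Each trial's lagged Gram matrix is eigendecomposed once;
training at every λ — and at every permuted envelope in the null — reuses
the factorization, making the 100-iteration permutation null roughly as
cheap as a single grid search.

*Forward refit.* `forward_lag_profile` fits, by least squares, the causal
kernel predicting each channel from the lagged envelope and returns the RMS
weight across channels per lag. On synthetic tracking data its peak
recovers the planted forward-kernel peak; because the default kernel is
within 2 % of its maximum over ±10 ms, single-subject peak estimates at
SNR 1 jitter by a sample or two, so peak-recovery checks average the
profile over subjects before locating the maximum (the usual group-average
TRF practice).

## Permutation null (`permute`)

Each iteration reverses every envelope and applies an independent uniform
circular shift, then re-runs the full cross-validation (λ re-optimized,
mirroring the treatment of real data; a fixed-λ option exists). Reversal +
rotation preserve the sample multiset and magnitude spectrum, so the null
keeps the envelope's autocorrelation structure while destroying stimulus–
EEG alignment. The subject-level chance value is the mean over iterations
(default 100; tests and the acceptance script use 20–50 to bound runtime).
Calibration is verified empirically: with no planted tracking, the
empirical p-value of the real r against a 50-iteration null is uniform
across seeds and the type-I error at α = 0.05 is nominal.

## Periodogram PSD (`spectral`)

The one-sided rectangular-window periodogram P(f) = (Δt/N)|DFT|², with all
bins except DC and Nyquist doubled, normalized by the *original* sample
count N even when the DFT is zero-padded to a common length across
subjects (padding refines the frequency grid; it carries no power). The
implementation delegates to `scipy.signal.periodogram`, whose density
scaling equals this definition exactly; tests verify against a brute-force
DFT and Parseval's identity. Peak values are window maxima of
channel-averaged power (default 1 Hz windows); subject-level peak lists are
screened by the 1.5·IQR rule with midpoint-interpolated quartiles (the
convention matters only for tiny n, hence it is pinned and documented).
Boundary peaks (e.g. at the broadband filter edge) are reported, never
auto-excluded.

## Phase-amplitude coupling (`pac`)

*Extraction.* Zero-phase Hamming-window FIR bandpass filters (same design
rule as preprocessing; transition width 2 Hz, shrunk for low bands) around
phase centres 2–8 Hz (2 Hz-wide bands) and amplitude centres 17.5–42.5 Hz.
Amplitude bands are centre ± 5 Hz. The asymmetry is deliberate and
necessary: the envelope of a band of width B contains only fluctuations
slower than ≈ B (with a spectral null at B), so an amplitude band must be
at least twice as wide as the fastest phase frequency of interest for
theta-rate coupling to be measurable at all. A 5 Hz-wide amplitude band
cannot, mathematically, exhibit 5 Hz amplitude modulation. The narrower
tiling convention remains available (`amp_bw=5`).

*Statistic.* MI = |mean(A·e^{iφ})| in sliding 5 s windows with 2.5 s
overlap. Surrogates circularly rotate the channel's full amplitude series
(200 iterations, evenly spaced offsets with a seeded common start, minimum
1 s) and re-evaluate every window, so each window is compared against
amplitude material from the whole recording rather than the ~10
statistically independent rotations available inside one 5 s window.
nMI = (MI − surrogate mean)/surrogate SD per window.

*Significance.* A window must exceed the one-sided 95 % Gaussian bound of
its surrogates *and* survive family-wise correction across the cell's
windows. The default correction is the max-statistic permutation test:
surrogate nMIs (leave-one-out studentized) are maximized across windows per
iteration, and a window is kept if its exact permutation p-value against
that maximum distribution is ≤ α. This controls FWE under exchangeability
regardless of the MI null's shape — which is Rayleigh-like, so step-down
corrections based on Gaussian tail probabilities at p ≈ 10⁻⁴ are badly
anticonservative here (measured family-wise error of 30–45 % on
no-coupling data); Holm–Bonferroni on Gaussian p-values is retained as an
option (`fwe_method="holm"`). Three implementation details protect
exchangeability between the real and rotated series, each worth percents
of family-wise error: evenly spaced rotation offsets (clustered random
offsets create near-duplicate surrogate columns), re-evaluation of the 1–2
windows per rotation that straddle the wrap seam on contiguous segments,
and trimming of filter transients plus a 1.5 s guard for the FFT Hilbert
transform's slowly decaying edge ringing (which is shared between a
channel's phase and amplitude series and correlates their aligned
windows). Measured family-wise error on no-coupling data is ≈ 5 %.

*Aggregation.* Surviving windows are averaged per (channel, phase centre,
amplitude centre) cell; cells with no surviving window are flagged missing.
Group-level summaries take the maximum cell mean per channel within four
groupings — delta (centres 2–3 Hz) or theta (4–8 Hz) phase × beta (centres
< 30 Hz) or gamma (≥ 30 Hz) amplitude; the shared 4 Hz phase edge goes to
theta and the 27.5/32.5 Hz amplitude centres to beta/gamma respectively
(configurable).

*Known limitation.* Under strict FWE, every surviving window exceeds the
max-statistic threshold (≈ 4.3 nMI at 116 windows), so a cell's mean over
surviving windows is threshold-truncated: a genuinely coupled cell with
dozens of surviving windows averages ≈ 5–6, while a null cell with one
lucky window can land in the same range. At the synthetic study conditions
(depth-1 coupling, 300 s, 200 surrogates) the coupled grouping is maximal
in roughly 85 % of subjects rather than always; the per-window nMI ceiling
is set by the ≈ 10 independent samples a 5 s window offers at 2 Hz phase
bandwidth and does not improve with planted coupling strength.

## Synthetic data (`synth`)

The generator reproduces the statistical structure the analysis assumes,
at the emulated study design: 128 channels (Fibonacci-lattice positions on
the upper unit hemisphere), 83 phrases of mean length 4.23 s (SD 0.88)
each repeated up to 3 times, a 5-minute rest recording, and synthesis at
the 100 Hz post-downsampling rate (1000 Hz available for resampling
tests). Tests and the acceptance script scale the channel and phrase
counts down (4–8 channels, 6–20 phrases) to keep runtimes at desk scale;
all rates, durations and depths stay at the study values.

* *Envelopes* are rectified sums of cycle-jittered (±10 %) sinusoids at the
  requested modulation rates (defaults 2.2 and 4.4 Hz, the rhythmic rates
  of sung nursery rhymes) plus weak pink noise; their modulation spectra
  peak within ±0.3 Hz of the requested rates.
* *Tracking EEG* is the mean-removed envelope convolved with a causal
  gamma-shaped kernel (unit peak at 80 ms, support within 250 ms), spread
  over channels by a smooth positive topography (affine in sensor
  position), plus 1/f^slope background noise (spectrally shaped white
  noise, slope 1 by default) scaled per channel to the requested SNR. The
  subject's topography is a function of the config seed; background noise
  varies per trial via `noise_seed`.
* *PAC signals* plant a noisy narrowband slow oscillation (bandpass noise,
  2 Hz band around the phase rate, shared across channels) whose analytic
  phase modulates the amplitude (1 + depth·cos φ) of a broadband
  high-frequency carrier (bandpass noise ± 6 Hz around the amplitude rate,
  independent per channel), with the coupling depth decaying linearly
  across channels so channel 0 is strongest. Both stochastic choices are
  load-bearing: a strictly sinusoidal phase makes the MI a Fourier
  magnitude of the amplitude series — invariant under circular rotation,
  degenerating the surrogate null — and a pure-tone carrier would have
  constant amplitude at depth 0 while its AM sidebands would fall outside
  the analysis bands. Real slow rhythms and gamma activity are noisy and
  broadband in exactly this way.
* *Rest* is 1/f background plus narrowband alpha (2 Hz band of noise at
  the configured frequency, default 10 Hz, variance = `alpha_power`).

What the generator does *not* emulate: ocular/cardiac artifacts (the
corresponding cleaning steps are out of scope), evoked transients at
phrase onsets, non-stationarity across the session, volume-conduction
mixing beyond a smooth topography, and line noise. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
signal model, not robustness to every artifact class in real recordings.

## Preprocessing (`preprocess`)

Zero-phase band filtering uses odd-length linear-phase Hamming-window FIR
kernels (order ⌈3.3·fs/transition⌉ rounded up to even; transition 2 Hz)
applied by centred convolution, which keeps the half-amplitude (−6 dB)
point at the cutoffs — a forward–backward application would square the
response to −12 dB there. Band presets: broadband 0.5–45 Hz; delta, theta
and alpha acquired with cutoffs 0–5, 3–9 and 7–13 Hz. Downsampling is
polyphase. Bad channels are those whose per-channel kurtosis or mean
Gaussian negative log-likelihood (fit to the pooled data) deviates more
than 3 SD from the across-channel mean — non-robust z-scores, which is the
simplest reading of the criterion and is flagged here; zero-variance
channels are always flagged. Repairs use spherical-spline interpolation
(Perrin kernel, stiffness m = 4, 7 Legendre terms, least-squares solve
since the truncated kernel matrix is rank-deficient at 128 electrodes).
Epoching re-detects and repairs bad channels per epoch with the same rule,
logging repairs per epoch. Repetitions of a phrase are averaged after
truncation to the shortest length (alignment to phrase onset preserved).

## Envelope conditioning (`envelope`)

Hilbert magnitude of the full-band audio, then 6th-order Butterworth
lowpass at 15 Hz and 9th-order highpass at 0.5 Hz — realized as
second-order sections and applied forward–backward. Zero-phase application
is a deliberate choice where the source procedure is ambiguous: it
preserves the envelope–EEG temporal alignment on which lagged decoding
depends, at the cost of doubling the effective filter order. Envelopes are
RMS-normalized and polyphase-resampled to the EEG rate.

## Pipeline (`pipeline`)

`run_subject` executes simulate → preprocess (broadband filter, optional
downsample, bad-channel repair, average reference) → per-band decode +
permutation null → PSD peaks (stimulus vs rest) → PAC on the concatenated
epochs, with results cached on disk keyed by a SHA-256 hash of the config
(reruns with unchanged config are byte-identical cache hits).
`summarize_group` emits mean/SEM tables per band and PAC grouping for
external inferential statistics; group ANOVAs and Bayes factors are
deliberately not computed here.

## Problem sizes

Default test and acceptance runs use: 20 trials of ~4 s at 100 Hz and 8
channels for decoding (nulls of 20–50 iterations, 20–50 seeds); 300 s,
4-channel recordings for PAC (full 7 × 6 grid, 200 surrogates, ~115
windows); 83 phrases × 3 repetitions for the epoch-arithmetic checks.
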