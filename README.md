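# cortrack

Cortical tracking of speech envelopes in EEG: backward temporal-response-
function (TRF) stimulus reconstruction with a permutation null, periodogram
power-spectral-density (PSD) peak analysis, and phase-amplitude coupling
(PAC) via the surrogate-normalized modulation index — plus a seeded
synthetic-data generator that plants known envelope tracking and coupling so
every stage of the pipeline can be validated by parameter recovery.

The package is aimed at auditory/developmental EEG researchers who study how
cortical activity in the delta (0.5–4 Hz), theta (4–8 Hz) and alpha
(8–12 Hz) bands tracks the amplitude envelope of naturalistic, quasi-rhythmic
speech (e.g. sung or chanted nursery rhymes), and how low-frequency phase
organizes beta/gamma amplitudes.

## The analyses

**Stimulus reconstruction (backward mTRF).** A linear decoder g(τ, n) maps
the multichannel neural response r(t, n) at lags τ ∈ [0, 250] ms back to the
stimulus envelope s(t):

    ŝ(t) = Σ_n Σ_τ r(t + τ, n) · g(τ, n)

Decoders are trained by ridge regression, (XᵀX + λI)w = Xᵀs, with λ chosen
from a 12-point grid (10⁻³ … 10⁸) by leave-one-out cross-validation over
phrase-aligned trials: per fold one decoder is trained per training trial,
the weight matrices are averaged, and the held-out trial's reconstruction is
scored with Pearson's r. The reported statistic is the mean held-out r at
the smallest near-optimal λ.

**Permutation null.** Chance-level reconstruction is estimated by decoding
envelopes that were time-reversed and circularly shifted by a random offset
(which preserves each envelope's sample distribution and magnitude spectrum),
iterated (default 100×) with the full cross-validation re-run each time.

**PSD peaks.** Each channel's one-sided rectangular-window periodogram
P(f) = (Δt/N)|Σ xₙ e^(−j2πfΔtn)|², with non-DC/non-Nyquist bins doubled,
is computed on the concatenated phrase epochs and on rest; peak values are
the maximum channel-averaged power in 1 Hz windows around chosen centre
frequencies, screened across subjects with the 1.5·IQR quartile rule.

**PAC (normalized modulation index).** Low-frequency phase (centres 2–8 Hz)
and high-frequency amplitude (centres 17.5–42.5 Hz) are extracted with
zero-phase FIR filters; the coupling in sliding 5 s windows is
MI = |mean(A·e^{iφ})|, z-scored against 200 circular-rotation surrogates
(nMI). Windows must beat the one-sided 95 % surrogate bound and a
max-statistic permutation correction across windows; surviving windows are
averaged per (channel, phase, amplitude) cell and the strongest channel per
delta/theta × beta/gamma grouping is reported.

## Worked example

Simulate a subject whose EEG tracks quasi-rhythmic envelopes (modulation
peaks near 2.2 and 4.4 Hz) through a known causal kernel, then decode:

```python
import numpy as np
from cortrack import (SynthConfig, gen_envelope, gen_tracking_eeg,
                      cross_validate, null_distribution)

cfg = SynthConfig(n_channels=8, fs=100.0, trf_snr=1.0, seed=0)
epochs, envelopes = [], []
for i in range(20):
    env = gen_envelope(4.0, 100.0, (2.2, 4.4), seed=i)
    eeg = gen_tracking_eeg(env, cfg, noise_seed=i)
    epochs.append(eeg.data)
    envelopes.append(env.samples)

cv = cross_validate(epochs, envelopes, fs=100.0)
null = null_distribution(epochs, envelopes, n_iter=20, seed=1, fs=100.0)
print(f"real r = {cv.mean_r:.3f} at lambda = {cv.chosen_lambda:g}; "
      f"null r = {null.null_mean_r:.3f} (95th pct {null.percentile(95):.3f})")
```

Output:

```
real r = 0.820 at lambda = 100; null r = 0.044 (95th pct 0.136)
```

The decoder reconstructs the envelope far above its permutation null
(r ≈ 0.82 vs ≈ 0.04): the planted envelope code in the synthetic EEG is
recovered. With `trf_snr=0` the real r falls inside the null distribution.

The same stages are available from a shell via the `cortrack` CLI
(`simulate`, `preprocess`, `envelope`, `decode`, `permute`, `psd`, `pac`,
`run`, `summarize`); see `cortrack --help`.

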