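"""Shared fixtures and synthetic-subject helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cortrack import SynthConfig, gen_envelope, gen_layout, gen_tracking_eeg
from cortrack.core import ChannelLayout, EEGRecording

FS = 100.0


@pytest.fixture(scope="session")
def layout128() -> ChannelLayout:
    return gen_layout(128, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def single_channel_recording(x: np.ndarray, fs: float = FS) -> EEGRecording:
    lay = ChannelLayout(("E1",), np.array([[0.0, 0.0, 1.0]]))
    return EEGRecording(np.atleast_2d(x), fs, lay)


def multi_channel_recording(data: np.ndarray, fs: float = FS) -> EEGRecording:
    return EEGRecording(data, fs, gen_layout(data.shape[0], seed=0))


def make_tracking_subject(
    seed: int,
    snr: float = 1.0,
    n_trials: int = 20,
    n_channels: int = 8,
    trial_dur: float = 4.0,
    fs: float = FS,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One simulated subject: per-trial EEG epochs and their envelopes.

    The subject's topography is fixed by ``seed``; the background noise
    varies per trial.
    """
    cfg = SynthConfig(n_channels=n_channels, fs=fs, trf_snr=snr, seed=seed)
    epochs, envs = [], []
    for i in range(n_trials):
        env = gen_envelope(trial_dur, fs, (2.2, 4.4), seed=1000 * seed + i)
        rec = gen_tracking_eeg(env, cfg, noise_seed=i)
        epochs.append(rec.data)
        envs.append(env.samples)
    return epochs, envs
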