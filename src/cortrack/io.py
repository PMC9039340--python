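"""On-disk formats: raw float binary + JSON sidecar recordings, CSV envelopes
and annotation tables.

A recording is stored as little-endian float32 samples (channel-major) in
``<stem>.dat`` with a ``<stem>.json`` sidecar holding the sampling rate,
channel table and provenance log.  Envelopes are 2-column CSV
(``time_s, amplitude``); annotations are CSV with columns
``phrase_id, repetition, onset_s, offset_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelLayout, EEGRecording, StimulusEnvelope

ANNOTATION_COLUMNS = ["phrase_id", "repetition", "onset_s", "offset_s"]


def write_recording(rec: EEGRecording, stem: str | Path) -> Path:
    """Write ``<stem>.dat`` (float32, channel-major) and ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data32 = rec.data.astype("<f4")
    data32.tofile(stem.with_suffix(".dat"))
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "channel_major",
        "units": "uV",
        "channels": [
            {"id": cid, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for cid, p in zip(rec.layout.ids, rec.layout.positions)
        ],
        "meta": rec.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".dat")


def read_recording(stem: str | Path) -> EEGRecording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".dat"), dtype=sidecar["dtype"])
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"]).astype(float)
    layout = ChannelLayout(
        ids=tuple(c["id"] for c in sidecar["channels"]),
        positions=np.array([[c["x"], c["y"], c["z"]] for c in sidecar["channels"]]),
    )
    return EEGRecording(data=data, fs=sidecar["fs"], layout=layout, meta=sidecar["meta"])


def write_envelope(env: StimulusEnvelope, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(env.n_samples) / env.fs
    pd.DataFrame({"time_s": t, "amplitude": env.samples}).to_csv(path, index=False)
    return path


def read_envelope(path: str | Path, phrase_id: str = "") -> StimulusEnvelope:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("envelope CSV must hold at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return StimulusEnvelope(samples=df["amplitude"].to_numpy(), fs=fs, phrase_id=phrase_id)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotations[ANNOTATION_COLUMNS].to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as a float mono waveform in [-1, 1] plus its rate."""
    from scipy.io import wavfile

    fs, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        info = np.iinfo(np.asarray(raw).dtype)
        data = data / max(abs(info.min), info.max)
    return data, float(fs)
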