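"""Core in-memory containers shared by the pipeline stages.

The central objects are :class:`EEGRecording` (a channels x samples array in
microvolts with its sensor layout), :class:`EpochSet` (phrase-aligned segments
with repetition bookkeeping) and :class:`StimulusEnvelope` (a non-negative
amplitude time series aligned to one phrase).  All pipeline operations return
new objects and append a provenance entry to ``meta`` so that the parameter
set of a result is fully reconstructable from the object itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "ChannelLayout",
    "EEGRecording",
    "Epoch",
    "EpochSet",
    "StimulusEnvelope",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode labels and unit-sphere positions.

    Parameters
    ----------
    ids : list of str
        Unique channel labels.
    positions : ndarray, shape (n_channels, 3)
        Cartesian coordinates on the unit sphere (head-centred).
    """

    ids: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ids", tuple(self.ids))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.ids) != pos.shape[0]:
            raise ValueError("number of ids must match number of positions")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("channel ids must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("channel positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "ChannelLayout":
        idx = np.asarray(idx)
        return ChannelLayout(
            ids=tuple(self.ids[i] for i in idx), positions=self.positions[idx]
        )


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    ``data`` is channels x samples in microvolts; ``fs`` the sampling rate in
    Hz; ``layout`` the sensor geometry; ``meta`` an append-only provenance log
    of ``{"op": name, **params}`` dictionaries.
    """

    data: np.ndarray
    fs: float
    layout: ChannelLayout
    meta: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("channel count does not match layout")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, op: str, **params: Any) -> "EEGRecording":
        """Return a copy holding ``data`` with ``op`` appended to the log."""
        return EEGRecording(
            data=data,
            fs=params.pop("fs", self.fs),
            layout=params.pop("layout", self.layout),
            meta=self.meta + [{"op": op, **params}],
        )


@dataclass
class Epoch:
    """One phrase-aligned EEG segment (channels x samples)."""

    phrase_id: str
    repetition: int
    data: np.ndarray


@dataclass
class EpochSet:
    """Phrase-aligned EEG segments with per-epoch interpolation log.

    ``interp_log`` maps ``(phrase_id, repetition)`` to the list of channel
    labels that were interpolated within that epoch only.
    """

    epochs: list[Epoch]
    fs: float
    layout: ChannelLayout
    interp_log: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    meta: list[dict[str, Any]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def phrase_ids(self) -> list[str]:
        return [e.phrase_id for e in self.epochs]


@dataclass
class StimulusEnvelope:
    """Amplitude envelope of one phrase's audio, s(t), sampled at ``fs``."""

    samples: np.ndarray
    fs: float
    phrase_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("envelope samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "StimulusEnvelope":
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)
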