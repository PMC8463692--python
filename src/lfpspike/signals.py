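"""Multi-channel time-series containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .array_geometry import ElectrodeArrayMap


@dataclass
class RawRecording:
    """Broadband extracellular recording, channels x samples.

    ``fs`` is the raw sampling rate (24.4-30 kHz for the real arrays;
    desk-scale simulations use lower rates).  ``channel_ids`` index into
    an :class:`~lfpspike.array_geometry.ElectrodeArrayMap` when geometry
    matters.
    """

    fs: float
    channel_ids: np.ndarray
    signal: np.ndarray
    array_map: ElectrodeArrayMap | None = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.channel_ids = np.asarray(self.channel_ids)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != self.channel_ids.size:
            raise ValueError(
                f"{self.signal.shape[0]} signal rows vs "
                f"{self.channel_ids.size} channel ids"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ContinuousSignal:
    """Derived continuous signal (LFP or ESA) at 1 kHz.

    ``provenance`` records the filter chain that produced the signal,
    one human-readable entry per processing step.
    """

    kind: str  # "lfp" | "esa"
    fs: float
    channel_ids: np.ndarray
    signal: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.channel_ids = np.asarray(self.channel_ids)
        if self.signal.shape[0] != self.channel_ids.size:
            raise ValueError("channel id / signal row mismatch")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs
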