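"""Windowed feature and target series on a common 256 ms / 50 ms-hop grid.

Six LFP features per channel -- the local motor potential (LMP, a
moving-average of the LFP amplitude) and mean spectral power in the
delta, theta, alpha, beta and gamma bands -- plus the target series:
the ESA feature (moving-averaged ESA) and SUA/MUA spike rates.

All features share one :class:`WindowGrid`: 256 ms windows overlapped
by 206 ms, i.e. one sample every 50 ms.  Feature timestamps sit at the
window END (causal convention).

Numerical notes
---------------
The short-time spectrum uses a 256-point Hann-tapered transform at
1 kHz, giving a 3.906 Hz bin spacing.  Band membership is half-open
[low, high) with the DC bin excluded, so at this resolution delta,
theta and alpha each contain exactly ONE bin (3.9, 7.8 and 11.7 Hz
respectively); beta holds 4 bins and gamma 18.  An ``nfft`` argument
enables zero padding when finer band resolution is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signals import ContinuousSignal

#: Canonical LFP frequency bands, Hz (gamma's upper edge follows the
#: LFP low-pass cutoff; see :func:`lfp_feature_matrix`).
LFP_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

LFP_FEATURE_TYPES = ("lmp", "delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid over a 1 kHz signal.

    ``timestamps_s`` are window end-times; window i covers samples
    [i*hop, i*hop + width).
    """

    width_ms: float
    hop_ms: float
    fs: float
    n_windows: int

    @property
    def overlap_ms(self) -> float:
        return self.width_ms - self.hop_ms

    @property
    def width_samples(self) -> int:
        return int(round(self.width_ms * self.fs / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_ms * self.fs / 1000.0))

    @property
    def start_indices(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.hop_samples

    @property
    def start_times_s(self) -> np.ndarray:
        return self.start_indices / self.fs

    @property
    def timestamps_s(self) -> np.ndarray:
        return (self.start_indices + self.width_samples) / self.fs


def sliding_window_grid(
    duration_s: float,
    fs: float = 1000.0,
    width_ms: float = 256.0,
    hop_ms: float = 50.0,
) -> WindowGrid:
    """Grid of contiguous, equally spaced, fully contained windows.

    The window count is floor((T_ms - width)/hop) + 1; a 10 s signal at
    the default 256/50 ms setting yields 195 windows.
    """
    t_ms = duration_s * 1000.0
    if t_ms < width_ms:
        raise ValueError(
            f"duration {duration_s} s shorter than one {width_ms} ms window"
        )
    n = int(np.floor((t_ms - width_ms) / hop_ms)) + 1
    return WindowGrid(width_ms=width_ms, hop_ms=hop_ms, fs=fs, n_windows=n)


def _signal_values(x: ContinuousSignal | np.ndarray, grid: WindowGrid) -> np.ndarray:
    if isinstance(x, ContinuousSignal):
        if abs(x.fs - grid.fs) > 1e-9:
            raise ValueError(f"signal at {x.fs} Hz but grid expects {grid.fs} Hz")
        v = x.signal
    else:
        v = np.asarray(x, dtype=float)
    last_needed = grid.start_indices[-1] + grid.width_samples
    if v.shape[-1] < last_needed:
        raise ValueError("window grid extends beyond the signal")
    return v


def _window_view(v: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """(..., n_windows, width_samples) read-only view."""
    sw = np.lib.stride_tricks.sliding_window_view(v, grid.width_samples, axis=-1)
    return sw[..., grid.start_indices, :]


def moving_average_feature(
    x: ContinuousSignal | np.ndarray, grid: WindowGrid
) -> np.ndarray:
    """Per-window arithmetic mean (rectangular window).

    Used both for the LMP (on LFP) and for the ESA feature (on ESA).
    Returns shape (..., n_windows).
    """
    v = _signal_values(x, grid)
    return _window_view(v, grid).mean(axis=-1)


def band_power_features(
    lfp: ContinuousSignal | np.ndarray,
    grid: WindowGrid,
    bands: Mapping[str, tuple[float, float]] | None = None,
    nfft: int | None = None,
) -> dict[str, np.ndarray]:
    """Hann-tapered short-time power averaged over each band's bins.

    Per window: one-sided power spectrum of the Hann-weighted segment;
    per band: mean of |X(f)|^2 over bins with low <= f < high, DC
    excluded.  A band containing no bins at the current resolution
    raises (pass ``nfft`` to zero-pad instead).
    """
    bands = dict(LFP_BANDS if bands is None else bands)
    v = _signal_values(lfp, grid)
    w = np.hanning(grid.width_samples)
    segs = _window_view(v, grid) * w
    n = nfft or grid.width_samples
    spec = np.fft.rfft(segs, n=n, axis=-1)
    psd = spec.real**2 + spec.imag**2
    freqs = np.fft.rfftfreq(n, 1.0 / grid.fs)
    out: dict[str, np.ndarray] = {}
    for name, (low, high) in bands.items():
        mask = (freqs >= low) & (freqs < high) & (freqs > 0)
        if not mask.any():
            raise ValueError(
                f"band {name} [{low}, {high}) Hz holds no bins at "
                f"{grid.fs / n:.3f} Hz resolution; increase nfft to zero-pad"
            )
        out[name] = psd[..., mask].mean(axis=-1)
    return out


def spike_rate_feature(spike_times_s: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Windowed spike rate in Hz: count in [start, end) / window length.

    The half-open interval avoids double counting a spike landing on
    the shared edge of adjacent windows.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    starts = grid.start_times_s
    ends = starts + grid.width_ms / 1000.0
    counts = np.searchsorted(t, ends, side="left") - np.searchsorted(t, starts, side="left")
    return counts / (grid.width_ms / 1000.0)


def select_active_units(
    trains: Sequence[np.ndarray], duration_s: float, min_rate_hz: float = 0.5
) -> np.ndarray:
    """Indices of units whose session-wide rate strictly exceeds the floor.

    The 0.5 Hz inclusion threshold is applied over the full session,
    before any block split; "exceeding" is read strictly, so a unit at
    exactly 0.5 Hz is dropped.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rates = np.array([len(t) / duration_s for t in trains])
    return np.flatnonzero(rates > min_rate_hz)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean/sd estimated on training rows (population sd)."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.std


def standardize(
    values: np.ndarray, train_rows: np.ndarray | None = None
) -> tuple[np.ndarray, StandardizationParams]:
    """Z-transform columns using statistics from ``train_rows`` only.

    Population sd (ddof 0); a zero-variance column is guarded by
    sd := 1, so constant columns standardize to all-zeros.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite values cannot be standardized")
    train = v if train_rows is None else v[train_rows]
    if train.shape[0] == 0:
        raise ValueError("empty training rows")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    params = StandardizationParams(mean=mu, std=sd)
    return params.apply(v), params


# ---------------------------------------------------------------------------
# feature / target matrices


@dataclass(frozen=True)
class FeatureColumn:
    channel: int
    feature: str  # "lmp" or a band name
    band_hz: tuple[float, float] | None = None


@dataclass(frozen=True)
class TargetColumn:
    signal_type: str  # "esa" | "sua" | "mua"
    channel: int
    unit_id: int | None = None


def _check_matrix(values: np.ndarray, columns: tuple) -> None:
    if values.ndim != 2:
        raise ValueError("matrix values must be 2-D (rows x columns)")
    if values.shape[1] != len(columns):
        raise ValueError("column descriptor count does not match values")
    if len(set(columns)) != len(columns):
        raise ValueError("duplicate column descriptors")


@dataclass
class FeatureMatrix:
    """n x p predictor matrix with per-column provenance."""

    values: np.ndarray
    columns: tuple[FeatureColumn, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(self.columns)
        _check_matrix(self.values, self.columns)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted({c.channel for c in self.columns}))

    @property
    def feature_types(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.columns:
            if c.feature not in seen:
                seen.append(c.feature)
        return tuple(seen)

    def select(
        self,
        channels: Iterable[int] | None = None,
        features: Iterable[str] | None = None,
    ) -> "FeatureMatrix":
        chs = None if channels is None else set(channels)
        fts = None if features is None else set(features)
        idx = [
            j
            for j, c in enumerate(self.columns)
            if (chs is None or c.channel in chs) and (fts is None or c.feature in fts)
        ]
        return FeatureMatrix(self.values[:, idx], tuple(self.columns[j] for j in idx))

    def to_frame(self) -> pd.DataFrame:
        names = [f"{c.feature}_ch{c.channel}" for c in self.columns]
        return pd.DataFrame(self.values, columns=names)


@dataclass
class TargetMatrix:
    """n x m response matrix (ESA / SUA / MUA) with per-column descriptors."""

    values: np.ndarray
    columns: tuple[TargetColumn, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(self.columns)
        _check_matrix(self.values, self.columns)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def select(self, signal_types: Iterable[str]) -> "TargetMatrix":
        want = set(signal_types)
        idx = [j for j, c in enumerate(self.columns) if c.signal_type in want]
        return TargetMatrix(self.values[:, idx], tuple(self.columns[j] for j in idx))

    def to_frame(self) -> pd.DataFrame:
        names = [
            f"{c.signal_type}_ch{c.channel}" + ("" if c.unit_id is None else f"_u{c.unit_id}")
            for c in self.columns
        ]
        return pd.DataFrame(self.values, columns=names)


def lfp_feature_matrix(
    lfp: ContinuousSignal,
    grid: WindowGrid,
    feature_types: Sequence[str] = LFP_FEATURE_TYPES,
    gamma_high_hz: float | None = None,
    nfft: int | None = None,
) -> FeatureMatrix:
    """Assemble the six LFP features for every channel on one grid.

    ``gamma_high_hz`` overrides the gamma band's upper edge so it can
    follow the LFP low-pass cutoff (100 Hz default, 300 Hz variant).
    Columns are ordered feature-major: all channels of the first
    feature type, then the next.
    """
    unknown = set(feature_types) - set(LFP_FEATURE_TYPES)
    if unknown:
        raise ValueError(f"unknown feature types {sorted(unknown)}")
    bands = {k: v for k, v in LFP_BANDS.items() if k in feature_types}
    if "gamma" in bands and gamma_high_hz is not None:
        bands["gamma"] = (bands["gamma"][0], float(gamma_high_hz))
    power = band_power_features(lfp, grid, bands, nfft=nfft) if bands else {}

    blocks: list[np.ndarray] = []
    cols: list[FeatureColumn] = []
    for ft in feature_types:
        if ft == "lmp":
            block = moving_average_feature(lfp, grid)
            band = None
        else:
            block = power[ft]
            band = bands[ft]
        blocks.append(block.T)  # (n_windows, n_channels)
        cols.extend(FeatureColumn(int(ch), ft, band) for ch in lfp.channel_ids)
    return FeatureMatrix(np.hstack(blocks), tuple(cols))


def spiking_target_matrix(
    grid: WindowGrid,
    esa: ContinuousSignal | None = None,
    sua_trains: Sequence[tuple[int, int, np.ndarray]] | None = None,
    mua_trains: Mapping[int, np.ndarray] | None = None,
) -> TargetMatrix:
    """Assemble ESA / SUA / MUA target series on a window grid.

    ``sua_trains`` holds (unit id, channel, spike times); ``mua_trains``
    maps channel -> merged spike times.  At least one source must be
    given.
    """
    blocks: list[np.ndarray] = []
    cols: list[TargetColumn] = []
    if esa is not None:
        blocks.append(moving_average_feature(esa, grid).T)
        cols.extend(TargetColumn("esa", int(ch)) for ch in esa.channel_ids)
    if sua_trains:
        rates = np.column_stack([spike_rate_feature(t, grid) for _, _, t in sua_trains])
        blocks.append(rates)
        cols.extend(TargetColumn("sua", int(ch), int(uid)) for uid, ch, _ in sua_trains)
    if mua_trains:
        items = sorted(mua_trains.items())
        rates = np.column_stack([spike_rate_feature(t, grid) for _, t in items])
        blocks.append(rates)
        cols.extend(TargetColumn("mua", int(ch)) for ch, _ in items)
    if not blocks:
        raise ValueError("no target sources given")
    return TargetMatrix(np.hstack(blocks), tuple(cols))
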