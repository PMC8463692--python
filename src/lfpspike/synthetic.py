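"""Synthetic broadband recordings with known LFP-spiking coupling.

The generator is a stand-in for real motor-cortex recordings: it is NOT
a biophysical model, merely the simplest stochastic process that gives
every pipeline stage a known ground truth.  Its ingredients:

* a slow latent "motor drive" z(t) -- white noise low-passed below
  ~2 Hz and standardized -- shared between the LFP band and the
  population firing rates;
* per-channel LFP at 1 kHz: g_c * z(t) plus narrowband oscillatory
  noise components plus pink (1/f) noise, where the coupling
  g_c = exp(-d(c, hotspot)/lambda) decays with distance from a hotspot
  electrode on the array;
* inhomogeneous-Poisson unit spike trains with rate
  r_u * max(0, 1 + beta_u * z(t)), sampled by thinning;
* a biphasic spike waveform (difference of two Gaussians, ~1.2 ms span,
  zero net area) of per-unit amplitude, added to the LFP upsampled to
  the raw rate, plus broadband white noise.

All randomness flows from one root seed through named substreams
(drive, unit parameters, spikes, LFP noise, raw noise), so each stage
is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .array_geometry import ElectrodeArrayMap, central_channel, distance_matrix
from .conditioning import zero_phase_filter
from .signals import RawRecording

DRIVE_FS = 1000.0


class SimulationConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class UnitParams:
    """Parameters of one simulated unit (neuron) on one channel."""

    channel: int
    base_rate_hz: float
    modulation_depth: float
    amplitude: float


@dataclass(frozen=True)
class SimulationConfig:
    """Generator configuration.

    Defaults emulate a 96-channel Utah-array session: broadband rate
    30 kHz, a <2 Hz shared drive, coupling length 1200 um (so the g_c
    range spans roughly 0.1-1 across the array from a central hotspot),
    alpha- and beta-band oscillatory noise uncoupled to the drive, and
    four units per channel with rates 5-20 Hz, modulation depths
    0.6-1.0 and log-uniform spike amplitudes.
    """

    n_channels: int = 96
    duration_s: float = 60.0
    fs_raw: float = 30000.0
    seed: int = 0
    drive_cutoff_hz: float = 2.0
    coupling_decay_um: float = 1200.0
    hotspot_channel: int | None = None  # None -> channel nearest array centroid
    band_components: tuple[tuple[float, float, float], ...] = (
        (8.0, 12.0, 0.35),   # (low Hz, high Hz, amplitude)
        (15.0, 30.0, 0.25),
    )
    pink_noise_sd: float = 0.3
    noise_sd: float = 0.5  # broadband white noise on the raw trace
    units_per_channel: int = 4
    base_rate_range_hz: tuple[float, float] = (5.0, 20.0)
    modulation_depth_range: tuple[float, float] = (0.6, 1.0)
    template_span_ms: float = 1.2
    amplitude_range: tuple[float, float] = (0.5, 4.0)  # log-uniform draw
    mua_amplitude_cutoff: float = 1.0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SimulationConfigError("duration must be positive")
        if self.fs_raw <= 600:
            raise SimulationConfigError("fs_raw must exceed 600 Hz (2 x 300 Hz)")
        if self.drive_cutoff_hz >= 500:
            raise SimulationConfigError("drive cutoff must stay below 500 Hz")
        if self.coupling_decay_um <= 0:
            raise SimulationConfigError("coupling decay length must be positive")
        if self.base_rate_range_hz[0] < 0:
            raise SimulationConfigError("unit rates must be non-negative")
        if self.units_per_channel < 0:
            raise SimulationConfigError("units_per_channel must be >= 0")
        if self.noise_sd < 0 or self.pink_noise_sd < 0:
            raise SimulationConfigError("noise levels must be non-negative")

    @classmethod
    def desk(cls, **overrides) -> "SimulationConfig":
        """Desk-scale preset: full 96-channel, 60 s session at 4 kHz raw.

        4 kHz keeps the 300 Hz ESA high-pass valid while making the
        whole pipeline run in seconds on one CPU.
        """
        base = cls(fs_raw=4000.0)
        return replace(base, **overrides)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    latent_drive: np.ndarray  # standardized, at DRIVE_FS
    fs_drive: float
    coupling: dict[int, float]  # channel id -> g_c in (0, 1]
    hotspot_channel: int
    units: list[UnitParams]
    spike_times: list[np.ndarray]  # seconds, per unit, sorted
    seed: int

    def sua_trains(self) -> list[tuple[int, int, np.ndarray]]:
        """Per-unit ground truth: (unit index, channel, spike times)."""
        return [(i, u.channel, t) for i, (u, t) in enumerate(zip(self.units, self.spike_times))]

    def mua_trains(self, amplitude_cutoff: float) -> dict[int, np.ndarray]:
        """Union of trains of units whose amplitude exceeds the cutoff.

        Emulates threshold-based multi-unit detection: small-amplitude
        units fall below the detection-equivalent cutoff and vanish.
        """
        merged: dict[int, list[np.ndarray]] = {}
        for u, t in zip(self.units, self.spike_times):
            if u.amplitude > amplitude_cutoff:
                merged.setdefault(u.channel, []).append(t)
        return {
            ch: np.sort(np.concatenate(ts)) if ts else np.empty(0)
            for ch, ts in merged.items()
        }


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def simulate_latent_drive(duration_s: float, cutoff_hz: float = 2.0, seed=0) -> np.ndarray:
    """Slow latent drive: low-passed white noise, standardized.

    Returns a series at 1 kHz with mean 0 and variance 1 (exactly, by
    construction).  ``cutoff_hz`` is the zero-phase 4th-order Butterworth
    low-pass cutoff.
    """
    if duration_s < 1:
        raise SimulationConfigError("drive duration must be at least 1 s")
    if cutoff_hz >= 500:
        raise SimulationConfigError("drive cutoff must stay below the 500 Hz Nyquist")
    rng = np.random.default_rng(_seedseq(seed))
    n = int(round(duration_s * DRIVE_FS))
    white = rng.standard_normal(n)
    z = zero_phase_filter(white, DRIVE_FS, order=4, cutoff=cutoff_hz, kind="low")
    z -= z.mean()
    sd = z.std()
    if sd == 0:
        raise SimulationConfigError("degenerate drive (zero variance)")
    return z / sd


def simulate_spike_trains(
    z: np.ndarray,
    units: Sequence[UnitParams],
    duration_s: float,
    seed=0,
    fs_drive: float = DRIVE_FS,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson trains with rate r_u * max(0, 1 + beta_u z).

    Sampling is by thinning against the per-unit maximum rate.  The
    rectified-linear link keeps the mean rate equal to r_u whenever
    clipping at zero is rare, which makes expected spike counts easy to
    reason about.
    """
    ss = _seedseq(seed)
    children = ss.spawn(len(units))
    out: list[np.ndarray] = []
    for u, child in zip(units, children):
        if u.base_rate_hz < 0:
            raise SimulationConfigError("negative base rate")
        rng = np.random.default_rng(child)
        rate = u.base_rate_hz * np.maximum(0.0, 1.0 + u.modulation_depth * z)
        rmax = float(rate.max(initial=0.0))
        if rmax <= 0:
            out.append(np.empty(0))
            continue
        n = rng.poisson(rmax * duration_s)
        t = np.sort(rng.uniform(0.0, duration_s, n))
        idx = np.minimum((t * fs_drive).astype(np.int64), z.size - 1)
        keep = rng.uniform(size=n) < rate[idx] / rmax
        out.append(t[keep])
    return out


def spike_template(fs: float, span_ms: float = 1.2) -> np.ndarray:
    """Biphasic waveform: difference of two Gaussians, zero net area.

    Peak normalized to 1; per-unit amplitudes scale it.  The zero
    integral keeps spikes out of the DC/low-frequency band, so spike
    leakage into the LFP chain stays negligible.
    """
    n = max(int(round(span_ms * fs / 1000.0)), 5)
    t_ms = np.arange(n) / fs * 1000.0
    c1, c2 = 0.35 * span_ms, 0.65 * span_ms
    s1, s2 = span_ms / 9.0, span_ms / 5.0
    g1 = np.exp(-0.5 * ((t_ms - c1) / s1) ** 2)
    g2 = np.exp(-0.5 * ((t_ms - c2) / s2) ** 2)
    w = g1 - g2 * (g1.sum() / g2.sum())  # exact zero sum before scaling
    return w / np.abs(w).max()


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance band-pass-filtered white noise."""
    y = zero_phase_filter(rng.standard_normal(n), fs, order=4, cutoff=(low, high), kind="band")
    sd = y.std()
    return y / sd if sd > 0 else y


def synthesize_raw_recording(
    config: SimulationConfig, amap: ElectrodeArrayMap
) -> tuple[RawRecording, SyntheticGroundTruth]:
    """Generate a broadband recording plus its complete ground truth.

    The 1 kHz per-channel LFP is linearly interpolated up to ``fs_raw``
    before spikes and white noise are added; the pipeline's subsequent
    100 Hz low-pass makes the interpolation artefacts negligible.
    """
    config.validate()
    ids = amap.channel_ids
    if len(ids) != config.n_channels:
        raise SimulationConfigError(
            f"array map has {len(ids)} channels, config wants {config.n_channels}"
        )
    hotspot = config.hotspot_channel
    if hotspot is None:
        hotspot = central_channel(amap)
    if hotspot not in amap.site_of_channel:
        raise SimulationConfigError(f"hotspot channel {hotspot} not in array map")

    ss = _seedseq(config.seed)
    ss_drive, ss_units, ss_spikes, ss_lfp, ss_raw = ss.spawn(5)

    z = simulate_latent_drive(config.duration_s, config.drive_cutoff_hz, ss_drive)
    n1k = z.size
    t1k = np.arange(n1k) / DRIVE_FS

    d = distance_matrix(amap, ids, [hotspot])[:, 0]
    g = np.exp(-d / config.coupling_decay_um)

    # per-channel LFP at 1 kHz
    rng_lfp = np.random.default_rng(ss_lfp)
    n_raw = int(round(config.duration_s * config.fs_raw))
    t_raw = np.arange(n_raw) / config.fs_raw
    raw = np.empty((len(ids), n_raw))
    for i in range(len(ids)):
        lfp_c = g[i] * z
        for low, high, amp in config.band_components:
            lfp_c = lfp_c + amp * _narrowband_noise(rng_lfp, n1k, DRIVE_FS, low, high)
        if config.pink_noise_sd > 0:
            lfp_c = lfp_c + config.pink_noise_sd * _pink_noise(rng_lfp, n1k)
        raw[i] = np.interp(t_raw, t1k, lfp_c)

    # units and spike trains
    rng_units = np.random.default_rng(ss_units)
    units: list[UnitParams] = []
    lo_a, hi_a = config.amplitude_range
    for ch in ids:
        for _ in range(config.units_per_channel):
            units.append(
                UnitParams(
                    channel=int(ch),
                    base_rate_hz=float(rng_units.uniform(*config.base_rate_range_hz)),
                    modulation_depth=float(rng_units.uniform(*config.modulation_depth_range)),
                    amplitude=float(math.exp(rng_units.uniform(math.log(lo_a), math.log(hi_a)))),
                )
            )
    trains = simulate_spike_trains(z, units, config.duration_s, ss_spikes)

    # add spike waveforms to the raw traces
    tmpl = spike_template(config.fs_raw, config.template_span_ms)
    half = tmpl.size // 2
    row_of = {int(ch): i for i, ch in enumerate(ids)}
    offs = np.arange(tmpl.size)
    for u, times in zip(units, trains):
        if times.size == 0:
            continue
        start = np.round(times * config.fs_raw).astype(np.int64) - half
        flat = start[:, None] + offs[None, :]
        vals = np.broadcast_to(u.amplitude * tmpl, flat.shape)
        valid = (flat >= 0) & (flat < n_raw)
        np.add.at(raw[row_of[u.channel]], flat[valid], vals[valid])

    if config.noise_sd > 0:
        rng_raw = np.random.default_rng(ss_raw)
        for i in range(len(ids)):  # channel loop caps peak memory
            raw[i] += config.noise_sd * rng_raw.standard_normal(n_raw)

    rec = RawRecording(
        fs=config.fs_raw,
        channel_ids=np.asarray(ids),
        signal=raw,
        array_map=amap,
    )
    truth = SyntheticGroundTruth(
        latent_drive=z,
        fs_drive=DRIVE_FS,
        coupling={int(ch): float(gc) for ch, gc in zip(ids, g)},
        hotspot_channel=int(hotspot),
        units=units,
        spike_times=trains,
        seed=config.seed,
    )
    return rec, truth
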