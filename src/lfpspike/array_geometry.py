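"""Utah-style microelectrode array geometry.

Models the 10 x 10, 400 um-pitch silicon electrode grid ("Utah array")
used for intracortical motor-cortex recordings.  Four of the 100 sites
are left unconnected by the standard wiring -- here, by default, the
four grid corners -- leaving 96 recording channels.

Downstream analyses (channel-importance maps, distance-trend
regressions) only ever consume pairwise interelectrode distances, so
channel numbering is simply row-major over connected sites; the physical
wire-bundle order of a real array is irrelevant here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Site = tuple[int, int]

#: Default Utah-array layout constants.
UTAH_ROWS = 10
UTAH_COLS = 10
UTAH_PITCH_UM = 400.0
UTAH_UNCONNECTED: tuple[Site, ...] = ((0, 0), (0, 9), (9, 0), (9, 9))


class ArrayConfigError(ValueError):
    """Raised for inconsistent electrode-array configurations."""


@dataclass(frozen=True)
class ElectrodeArrayMap:
    """Mapping from channel ids to electrode grid sites.

    Parameters
    ----------
    grid_rows, grid_cols
        Grid extent (10 x 10 for a Utah array).
    pitch_um
        Interelectrode spacing in micrometres (400 for a Utah array).
    site_of_channel
        Channel id -> (row, col).  Sites absent from this mapping are
        unconnected.
    """

    grid_rows: int
    grid_cols: int
    pitch_um: float
    site_of_channel: Mapping[int, Site]

    def __post_init__(self) -> None:
        seen: set[Site] = set()
        for ch, (r, c) in self.site_of_channel.items():
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ArrayConfigError(
                    f"channel {ch} site {(r, c)} outside "
                    f"{self.grid_rows}x{self.grid_cols} grid"
                )
            if (r, c) in seen:
                raise ArrayConfigError(f"site {(r, c)} mapped to more than one channel")
            seen.add((r, c))

    @property
    def n_channels(self) -> int:
        return len(self.site_of_channel)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.site_of_channel))

    @property
    def connected_sites(self) -> frozenset[Site]:
        return frozenset(self.site_of_channel.values())

    def is_connected(self, site: Site) -> bool:
        return tuple(site) in self.connected_sites

    def site(self, channel: int) -> Site:
        try:
            return self.site_of_channel[channel]
        except KeyError:
            raise KeyError(f"unknown channel id {channel!r}") from None

    def coords_um(self, channels: Iterable[int] | None = None) -> np.ndarray:
        """Physical (x, y) coordinates in um, one row per channel."""
        ids = self.channel_ids if channels is None else list(channels)
        rc = np.array([self.site(c) for c in ids], dtype=float)
        return rc * self.pitch_um

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "pitch_um": self.pitch_um,
            "channels": {str(ch): list(site) for ch, site in self.site_of_channel.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ElectrodeArrayMap":
        payload = json.loads(text)
        return cls(
            grid_rows=int(payload["grid_rows"]),
            grid_cols=int(payload["grid_cols"]),
            pitch_um=float(payload["pitch_um"]),
            site_of_channel={
                int(ch): (int(r), int(c)) for ch, (r, c) in payload["channels"].items()
            },
        )


def build_array_map(
    rows: int = UTAH_ROWS,
    cols: int = UTAH_COLS,
    pitch_um: float = UTAH_PITCH_UM,
    unconnected_sites: Sequence[Site] | None = UTAH_UNCONNECTED,
    n_channels: int | None = None,
) -> ElectrodeArrayMap:
    """Build an electrode-array map with row-major channel numbering.

    Channels are numbered 1..K over connected sites, scanning rows then
    columns.  ``unconnected_sites`` defaults to the four grid corners --
    the only 4-site choice consistent with a 0..4561 um distance range on
    the 10x10/400 um layout.

    Parameters
    ----------
    n_channels
        If given, the number of connected sites must equal this count.
    """
    if rows <= 0 or cols <= 0:
        raise ArrayConfigError("grid extent must be positive")
    if pitch_um <= 0:
        raise ArrayConfigError("pitch must be positive")
    unconnected = [tuple(s) for s in (unconnected_sites or ())]
    if len(set(unconnected)) != len(unconnected):
        raise ArrayConfigError("duplicate unconnected sites")
    for r, c in unconnected:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ArrayConfigError(f"unconnected site {(r, c)} outside grid")
    excluded = set(unconnected)
    mapping: dict[int, Site] = {}
    ch = 1
    for r in range(rows):
        for c in range(cols):
            if (r, c) in excluded:
                continue
            mapping[ch] = (r, c)
            ch += 1
    if n_channels is not None and len(mapping) != n_channels:
        raise ArrayConfigError(
            f"{rows}x{cols} grid with {len(excluded)} unconnected sites yields "
            f"{len(mapping)} channels, not the requested {n_channels}"
        )
    return ElectrodeArrayMap(rows, cols, pitch_um, mapping)


def distance_matrix(
    amap: ElectrodeArrayMap,
    channels_a: Iterable[int] | None = None,
    channels_b: Iterable[int] | None = None,
) -> np.ndarray:
    """Euclidean interelectrode distances in um, shape (len(a), len(b))."""
    xa = amap.coords_um(channels_a)
    xb = amap.coords_um(channels_b)
    diff = xa[:, None, :] - xb[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def interelectrode_distances(
    amap: ElectrodeArrayMap,
    channels_a: Iterable[int] | None = None,
    channels_b: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Long-form table of pairwise distances.

    Returns a DataFrame with columns ``channel_a``, ``channel_b``,
    ``distance_um``.  Distance is ``pitch * sqrt(drow^2 + dcol^2)``;
    symmetric, zero on the diagonal.
    """
    ids_a = list(amap.channel_ids if channels_a is None else channels_a)
    ids_b = list(amap.channel_ids if channels_b is None else channels_b)
    d = distance_matrix(amap, ids_a, ids_b)
    return pd.DataFrame(
        {
            "channel_a": np.repeat(ids_a, len(ids_b)),
            "channel_b": np.tile(ids_b, len(ids_a)),
            "distance_um": d.ravel(),
        }
    )


def max_interelectrode_distance(amap: ElectrodeArrayMap) -> float:
    """Maximum pairwise distance over connected sites, in um (float).

    On the corner-unconnected Utah layout this is 400 * sqrt(130) =
    4560.70... um, printed in the literature rounded to 4561 um.
    """
    return float(distance_matrix(amap).max())


def central_channel(amap: ElectrodeArrayMap) -> int:
    """Channel whose site lies nearest the centroid of connected sites."""
    ids = amap.channel_ids
    coords = amap.coords_um(ids)
    centroid = coords.mean(axis=0)
    return ids[int(np.argmin(((coords - centroid) ** 2).sum(axis=1)))]


def grid_for_channels(n_channels: int, pitch_um: float = UTAH_PITCH_UM) -> ElectrodeArrayMap:
    """Smallest near-square grid holding ``n_channels`` connected sites.

    96 channels map to the standard Utah layout (corners unconnected);
    other counts use a ceil(sqrt)-sized grid with trailing sites left
    unconnected.  Intended for desk-scale simulations.
    """
    if n_channels == 96:
        return build_array_map(n_channels=96, pitch_um=pitch_um)
    if n_channels <= 0:
        raise ArrayConfigError("need at least one channel")
    cols = math.ceil(math.sqrt(n_channels))
    rows = math.ceil(n_channels / cols)
    extra = rows * cols - n_channels
    trailing = [
        (rows - 1, cols - 1 - k) for k in range(extra)
    ]
    return build_array_map(rows, cols, pitch_um, trailing, n_channels=n_channels)
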