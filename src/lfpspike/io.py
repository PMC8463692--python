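"""HDF5 session container: one self-describing file per pipeline run.

Layout::

    /raw       channels x samples broadband signal; attrs: fs; channel_ids
    /truth     generator ground truth (latent drive, coupling, per-unit
               spike times as ragged datasets, parameters as attrs)
    /lfp /esa  derived 1 kHz signals; attrs: fs, kind, provenance
    /features  windowed predictor matrix + column-descriptor JSON
    /targets   windowed response matrix + column-descriptor JSON
    /model     fitted MLR (intercepts, coefficients, descriptors)
    /metrics   cross-validation records table (JSON, orient=split)

Root attrs carry the schema version, the seed and the array-map JSON.
Re-writing a stage replaces only that stage's groups.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .array_geometry import ElectrodeArrayMap
from .features import FeatureColumn, FeatureMatrix, TargetColumn, TargetMatrix
from .inference import MLRModel
from .signals import ContinuousSignal, RawRecording
from .synthetic import SyntheticGroundTruth, UnitParams

SCHEMA_VERSION = "1"

GROUPS = ("raw", "truth", "lfp", "esa", "features", "targets", "model", "metrics")


class SchemaError(RuntimeError):
    """Missing or inconsistent container structure."""


@dataclass
class SessionContainer:
    """In-memory view of one session's artifacts (all fields optional)."""

    raw: RawRecording | None = None
    truth: SyntheticGroundTruth | None = None
    lfp: ContinuousSignal | None = None
    esa: ContinuousSignal | None = None
    features: FeatureMatrix | None = None
    targets: TargetMatrix | None = None
    model: MLRModel | None = None
    metrics: pd.DataFrame | None = None
    array_map: ElectrodeArrayMap | None = None
    seed: int | None = None
    log: list[str] = field(default_factory=list)

    def present_groups(self) -> list[str]:
        return [g for g in GROUPS if getattr(self, g) is not None]


def _feature_cols_json(cols: tuple[FeatureColumn, ...]) -> str:
    return json.dumps(
        [[c.channel, c.feature, list(c.band_hz) if c.band_hz else None] for c in cols]
    )


def _feature_cols_from_json(text: str) -> tuple[FeatureColumn, ...]:
    return tuple(
        FeatureColumn(int(ch), ft, tuple(band) if band else None)
        for ch, ft, band in json.loads(text)
    )


def _target_cols_json(cols: tuple[TargetColumn, ...]) -> str:
    return json.dumps([[c.signal_type, c.channel, c.unit_id] for c in cols])


def _target_cols_from_json(text: str) -> tuple[TargetColumn, ...]:
    return tuple(
        TargetColumn(st, int(ch), None if uid is None else int(uid))
        for st, ch, uid in json.loads(text)
    )


def _write_continuous(f: h5py.File, name: str, sig: ContinuousSignal) -> None:
    g = f.create_group(name)
    g.create_dataset("signal", data=sig.signal)
    g.create_dataset("channel_ids", data=np.asarray(sig.channel_ids, dtype=np.int64))
    g.attrs["fs"] = sig.fs
    g.attrs["kind"] = sig.kind
    g.attrs["provenance"] = json.dumps(list(sig.provenance))


def _read_continuous(g: h5py.Group) -> ContinuousSignal:
    return ContinuousSignal(
        kind=str(g.attrs["kind"]),
        fs=float(g.attrs["fs"]),
        channel_ids=g["channel_ids"][()],
        signal=g["signal"][()],
        provenance=tuple(json.loads(g.attrs["provenance"])),
    )


def write_session(
    path,
    container: SessionContainer,
    groups: list[str] | None = None,
    mode: str = "a",
) -> None:
    """Persist (a subset of) the container; existing groups are replaced.

    ``groups=None`` writes every group present on the container.
    """
    groups = container.present_groups() if groups is None else list(groups)
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    with h5py.File(path, mode) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if container.seed is not None:
            f.attrs["seed"] = int(container.seed)
        if container.array_map is not None:
            f.attrs["array_map_json"] = container.array_map.to_json()
        if container.log:
            f.attrs["log"] = json.dumps(container.log)
        for g in groups:
            if g in f:
                del f[g]

        if "raw" in groups:
            raw = container.raw
            grp = f.create_group("raw")
            grp.create_dataset("signal", data=raw.signal)
            grp.create_dataset(
                "channel_ids", data=np.asarray(raw.channel_ids, dtype=np.int64)
            )
            grp.attrs["fs"] = raw.fs
        if "truth" in groups:
            truth = container.truth
            grp = f.create_group("truth")
            grp.create_dataset("latent_drive", data=truth.latent_drive)
            grp.attrs["fs_drive"] = truth.fs_drive
            grp.attrs["seed"] = truth.seed
            grp.attrs["hotspot_channel"] = truth.hotspot_channel
            chans = sorted(truth.coupling)
            grp.create_dataset("coupling_channels", data=np.asarray(chans, dtype=np.int64))
            grp.create_dataset(
                "coupling", data=np.asarray([truth.coupling[c] for c in chans])
            )
            units = grp.create_group("units")
            for i, (u, t) in enumerate(zip(truth.units, truth.spike_times)):
                ug = units.create_group(f"u{i:05d}")
                ug.create_dataset("spike_times", data=np.asarray(t, dtype=float))
                for k, v in dataclasses.asdict(u).items():
                    ug.attrs[k] = v
        if "lfp" in groups:
            _write_continuous(f, "lfp", container.lfp)
        if "esa" in groups:
            _write_continuous(f, "esa", container.esa)
        if "features" in groups:
            grp = f.create_group("features")
            grp.create_dataset("values", data=container.features.values)
            grp.attrs["columns"] = _feature_cols_json(container.features.columns)
        if "targets" in groups:
            grp = f.create_group("targets")
            grp.create_dataset("values", data=container.targets.values)
            grp.attrs["columns"] = _target_cols_json(container.targets.columns)
        if "model" in groups:
            model = container.model
            grp = f.create_group("model")
            grp.create_dataset("intercepts", data=model.intercepts)
            grp.create_dataset("coefficients", data=model.coefficients)
            if model.feature_columns is not None:
                grp.attrs["feature_columns"] = _feature_cols_json(model.feature_columns)
            if model.target_columns is not None:
                grp.attrs["target_columns"] = _target_cols_json(model.target_columns)
        if "metrics" in groups:
            grp = f.create_group("metrics")
            df = container.metrics
            grp.attrs["columns"] = json.dumps(list(df.columns))
            for col in df.columns:
                series = df[col]
                if series.dtype == object:
                    data = series.astype(str).to_numpy(dtype=h5py.string_dtype())
                else:
                    data = series.to_numpy()
                grp.create_dataset(f"col_{col}", data=data)


def read_session(path, require: list[str] | None = None) -> SessionContainer:
    """Load a session container, validating schema and shapes.

    ``require`` lists groups that must be present; a missing one raises
    :class:`SchemaError` naming the group.
    """
    out = SessionContainer()
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version mismatch: file has {version!r}, expected {SCHEMA_VERSION!r}"
            )
        for g in require or []:
            if g not in f:
                raise SchemaError(f"required group /{g} missing from {path}")
        if "seed" in f.attrs:
            out.seed = int(f.attrs["seed"])
        if "array_map_json" in f.attrs:
            out.array_map = ElectrodeArrayMap.from_json(f.attrs["array_map_json"])
        if "log" in f.attrs:
            out.log = json.loads(f.attrs["log"])

        if "raw" in f:
            grp = f["raw"]
            sig = grp["signal"][()]
            ids = grp["channel_ids"][()]
            if sig.shape[0] != ids.size:
                raise SchemaError("/raw signal shape inconsistent with channel_ids")
            out.raw = RawRecording(
                fs=float(grp.attrs["fs"]), channel_ids=ids, signal=sig,
                array_map=out.array_map,
            )
        if "truth" in f:
            grp = f["truth"]
            chans = grp["coupling_channels"][()]
            coupling = dict(zip(chans.tolist(), grp["coupling"][()].tolist()))
            units, trains = [], []
            for name in sorted(grp["units"]):
                ug = grp["units"][name]
                units.append(
                    UnitParams(
                        channel=int(ug.attrs["channel"]),
                        base_rate_hz=float(ug.attrs["base_rate_hz"]),
                        modulation_depth=float(ug.attrs["modulation_depth"]),
                        amplitude=float(ug.attrs["amplitude"]),
                    )
                )
                trains.append(ug["spike_times"][()])
            out.truth = SyntheticGroundTruth(
                latent_drive=grp["latent_drive"][()],
                fs_drive=float(grp.attrs["fs_drive"]),
                coupling=coupling,
                hotspot_channel=int(grp.attrs["hotspot_channel"]),
                units=units,
                spike_times=trains,
                seed=int(grp.attrs["seed"]),
            )
        if "lfp" in f:
            out.lfp = _read_continuous(f["lfp"])
        if "esa" in f:
            out.esa = _read_continuous(f["esa"])
        if "features" in f:
            grp = f["features"]
            out.features = FeatureMatrix(
                grp["values"][()], _feature_cols_from_json(grp.attrs["columns"])
            )
        if "targets" in f:
            grp = f["targets"]
            out.targets = TargetMatrix(
                grp["values"][()], _target_cols_from_json(grp.attrs["columns"])
            )
        if "model" in f:
            grp = f["model"]
            out.model = MLRModel(
                intercepts=grp["intercepts"][()],
                coefficients=grp["coefficients"][()],
                feature_columns=(
                    _feature_cols_from_json(grp.attrs["feature_columns"])
                    if "feature_columns" in grp.attrs
                    else None
                ),
                target_columns=(
                    _target_cols_from_json(grp.attrs["target_columns"])
                    if "target_columns" in grp.attrs
                    else None
                ),
            )
        if "metrics" in f:
            grp = f["metrics"]
            cols = json.loads(grp.attrs["columns"])
            data = {}
            for col in cols:
                arr = grp[f"col_{col}"][()]
                if arr.dtype.kind in ("O", "S"):
                    arr = np.array([s.decode() if isinstance(s, bytes) else s for s in arr])
                data[col] = arr
            out.metrics = pd.DataFrame(data)
    return out
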