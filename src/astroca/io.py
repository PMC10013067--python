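"""Configuration files and trace serialization.

Run configurations and morphology specifications are YAML (key-value plus
adjacency list); traces go to HDF5 (one group per species, datasets
``time``/``data``, column labels and metadata as attributes) or CSV, and
round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .morphology import Geometry, MorphologySpec
from .params import AstroParams
from .traces import TraceSet

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_morphology",
    "save_morphology",
    "write_traces",
    "read_traces",
]


@dataclass
class RunConfig:
    """Validated simulation run configuration with defaults filled in."""

    fixture: str = "chain15"       # chain15 | mesh30 | star:<n> | chain:<n>
    geometry: dict = field(default_factory=dict)
    astro: dict = field(default_factory=dict)
    synapse: dict = field(default_factory=dict)
    duration: float = 140.0
    dt: float = 1e-3
    burn_in: float = 20.0
    trials: int = 20
    seed: int = 0
    n_sigma: float = 2.0
    outdir: str = "results"

    def astro_params(self) -> AstroParams:
        try:
            return AstroParams(**self.astro)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid astro parameter override: {e}") from e

    def geometry_obj(self) -> Geometry:
        try:
            return Geometry(**self.geometry)
        except Exception as e:
            raise ConfigError(f"invalid geometry: {e}") from e

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**raw)
    if cfg.dt <= 0 or cfg.duration <= 0 or cfg.trials < 1:
        raise ConfigError("duration and dt must be positive, trials >= 1")
    # fail fast on bad overrides
    cfg.astro_params()
    cfg.geometry_obj()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def save_morphology(spec: MorphologySpec, geom: Geometry, path: str | Path) -> None:
    doc = {"geometry": dataclasses.asdict(geom), **spec.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_morphology(path: str | Path) -> tuple[MorphologySpec, Geometry]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("nodes", "links"):
        if key not in raw:
            raise ConfigError(f"morphology file missing {key!r}")
    geom = Geometry(**raw.get("geometry", {}))
    return MorphologySpec.from_dict(raw), geom


# ---------------------------------------------------------------------------
# Trace serialization
# ---------------------------------------------------------------------------


def write_traces(ts: TraceSet, path: str | Path, format: str = "hdf5") -> dict:
    """Serialize a TraceSet; returns a manifest of what was written."""
    path = Path(path)
    for arr in ts.data.values():
        if not np.isfinite(arr).all():
            raise ValueError("refusing to write non-finite traces")
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=ts.time)
            f.attrs["meta"] = json.dumps(ts.meta)
            for name, arr in ts.data.items():
                grp = f.create_group(name)
                grp.create_dataset("data", data=arr)
                grp.attrs["columns"] = json.dumps(ts.columns[name])
    elif format == "csv":
        frames = []
        for name, arr in ts.data.items():
            cols = ts.columns[name]
            for trial in range(arr.shape[0]):
                df = pd.DataFrame(arr[trial], columns=cols)
                df.insert(0, "time", ts.time)
                df.insert(0, "trial", trial)
                df.insert(0, "species", name)
                frames.append(df)
        long = pd.concat(frames, ignore_index=True)
        long.to_csv(path, index=False)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta_path.write_text(
            json.dumps({"meta": ts.meta, "columns": ts.columns}, indent=1)
        )
    else:
        raise ValueError(f"unknown trace format {format!r}")
    return {
        "path": str(path),
        "format": format,
        "species": sorted(ts.data),
        "columns": {k: list(v) for k, v in ts.columns.items()},
        "n_trials": ts.n_trials,
        "n_samples": int(ts.time.size),
    }


def read_traces(path: str | Path, format: str | None = None) -> TraceSet:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            time = f["time"][:]
            meta = json.loads(f.attrs["meta"])
            data, columns = {}, {}
            for name in f:
                if name == "time":
                    continue
                data[name] = f[name]["data"][:]
                columns[name] = json.loads(f[name].attrs["columns"])
        return TraceSet(time=time, data=data, columns=columns, meta=meta)
    if format == "csv":
        long = pd.read_csv(path)
        side = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        columns = {k: list(v) for k, v in side["columns"].items()}
        data = {}
        time = None
        for name, cols in columns.items():
            sub = long[long["species"] == name]
            trials = sorted(sub["trial"].unique())
            arrs = []
            for trial in trials:
                st = sub[sub["trial"] == trial].sort_values("time")
                arrs.append(st[cols].to_numpy())
                time = st["time"].to_numpy()
            data[name] = np.stack(arrs)
        return TraceSet(time=time, data=data, columns=columns, meta=side["meta"])
    raise ValueError(f"unknown trace format {format!r}")
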