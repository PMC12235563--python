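"""Serialization: experiment configs (YAML), spike rasters (TSV), run
manifests (JSON)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd
import yaml

from .drives import AperiodicBurst, DriveBurst, EvokedDrive
from .experiments import ExperimentConfig
from .network import (
    CellParams, ConnectionSpec, NetworkConfig, ReceptorKinetics,
)

__all__ = [
    "experiment_to_dict",
    "experiment_from_dict",
    "write_experiment_yaml",
    "read_experiment_yaml",
    "write_raster_tsv",
    "read_raster_tsv",
    "write_manifest",
    "file_digest",
]

_DRIVE_KINDS = {
    "evoked": EvokedDrive,
    "burst": DriveBurst,
    "aperiodic_burst": AperiodicBurst,
}


def _drive_to_dict(d) -> dict:
    for kind, cls in _DRIVE_KINDS.items():
        if isinstance(d, cls):
            out = {"kind": kind}
            out.update(asdict(d))
            if kind == "aperiodic_burst":
                out["window"] = list(d.window)
                if not isinstance(d.weights, dict):
                    out["weights"] = [dict(w) for w in d.weights]
            return out
    raise TypeError(f"unknown drive type {type(d).__name__}")


def _drive_from_dict(data: dict):
    data = dict(data)
    kind = data.pop("kind")
    cls = _DRIVE_KINDS[kind]
    if kind == "aperiodic_burst":
        data["window"] = tuple(data["window"])
        if isinstance(data["weights"], list):
            data["weights"] = tuple(data["weights"])
    return cls(**data)


def experiment_to_dict(config: ExperimentConfig) -> dict:
    net = config.network
    return {
        "name": config.name,
        "duration": config.duration,
        "n_trials": config.n_trials,
        "scaling_factor": config.scaling_factor,
        "smoothing_window_ms": config.smoothing_window_ms,
        "base_seed": config.base_seed,
        "dt": config.dt,
        "network": {
            "n_pyr_per_layer": net.n_pyr_per_layer,
            "n_basket_per_layer": net.n_basket_per_layer,
            "grid_spacing": net.grid_spacing,
            "space_constant": net.space_constant,
            "connection_table": [asdict(c) for c in net.connection_table],
            "cell_params": {
                pop: _cell_params_to_dict(cp)
                for pop, cp in sorted(net.cell_params.items())
            },
        },
        "drives": [_drive_to_dict(d) for d in config.drives],
    }


def _cell_params_to_dict(cp: CellParams) -> dict:
    d = asdict(cp)
    d["compartments"] = list(cp.compartments)
    d["apical_lengths"] = list(cp.apical_lengths)
    d["synapses"] = {rec: asdict(k) for rec, k in sorted(cp.synapses.items())}
    return d


def _cell_params_from_dict(d: dict) -> CellParams:
    d = dict(d)
    d["compartments"] = tuple(d["compartments"])
    d["apical_lengths"] = tuple(d["apical_lengths"])
    d["synapses"] = {
        rec: ReceptorKinetics(**k) for rec, k in d["synapses"].items()
    }
    return CellParams(**d)


def experiment_from_dict(data: dict) -> ExperimentConfig:
    net = data["network"]
    network = NetworkConfig(
        n_pyr_per_layer=net["n_pyr_per_layer"],
        n_basket_per_layer=net["n_basket_per_layer"],
        grid_spacing=net["grid_spacing"],
        space_constant=net["space_constant"],
        connection_table=tuple(
            ConnectionSpec(**c) for c in net["connection_table"]
        ),
        cell_params={
            pop: _cell_params_from_dict(cp)
            for pop, cp in net["cell_params"].items()
        },
    )
    return ExperimentConfig(
        name=data["name"],
        network=network,
        drives=tuple(_drive_from_dict(d) for d in data["drives"]),
        duration=data["duration"],
        n_trials=data["n_trials"],
        scaling_factor=data["scaling_factor"],
        smoothing_window_ms=data["smoothing_window_ms"],
        base_seed=data["base_seed"],
        dt=data["dt"],
    )


def write_experiment_yaml(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(experiment_to_dict(config), fh, sort_keys=True,
                       default_flow_style=False)


def read_experiment_yaml(path) -> ExperimentConfig:
    with open(path) as fh:
        return experiment_from_dict(yaml.safe_load(fh))


_RASTER_COLUMNS = ["trial", "cell_id", "population", "spike_time_ms"]


def write_raster_tsv(raster, path) -> None:
    """Write a spike raster (trial, cell_id, population, spike_time_ms)."""
    pd.DataFrame(raster, columns=_RASTER_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_raster_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _RASTER_COLUMNS:
        raise ValueError(f"unexpected raster columns {list(df.columns)!r}")
    return df


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: ExperimentConfig | None,
                   seed: int, outputs, wall_time_s: float,
                   overrides: dict | None = None) -> None:
    """One manifest per run: command, config echo, seed, version, output
    digests, wall time."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "wall_time_s": round(wall_time_s, 3),
        "overrides": overrides or {},
        "config": experiment_to_dict(config) if config is not None else None,
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
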