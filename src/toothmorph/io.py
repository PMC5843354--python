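"""Serialization: HDF5/CSV simulation states, YAML run configs,
run manifests, and ASCII PLY export of stress rods.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cells import GrowthConfig
from .experiments import RunConfig
from .state import (
    ROLE_NAMES,
    TISSUE_NAMES,
    AdhesionTable,
    MechanicalDefaults,
    SimulationState,
)

__all__ = [
    "save_state",
    "load_state",
    "run_config_to_dict",
    "run_config_from_dict",
    "load_run_config",
    "save_run_config",
    "RunManifest",
    "write_manifest",
    "stress_rods_to_ply",
]

_SCHEMA_VERSION = 1
_NODE_PARAMS = ("p_REC", "p_EQD", "p_ADD", "p_HOO", "p_EST", "p_ERP")


# ----------------------------------------------------------------------
# HDF5

def _save_h5(state: SimulationState, path) -> None:
    with h5py.File(path, "w", libver="earliest") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["time"] = state.time
        f.attrs["dim"] = state.dim

        def ds(name, data):
            f.create_dataset(name, data=data, track_times=False)

        ds("positions", state.positions)
        ds("role", state.role)
        ds("node_cell", state.node_cell)
        ds("fixed", state.fixed)
        for name in _NODE_PARAMS:
            ds(name, getattr(state, name))
        ds("expression", state.expression)
        ds("cell_tissue", state.cell_tissue)
        ds("cell_knot", state.cell_knot)
        ds("cell_phase", state.cell_phase)
        ds("cell_nodes", state.cell_nodes)
        ds("cell_EQS", state.cell_EQS)
        ds("adhesion", state.adhesion.b)


def _load_h5(path) -> SimulationState:
    with h5py.File(path, "r") as f:
        kwargs = dict(
            positions=f["positions"][...],
            role=f["role"][...],
            node_cell=f["node_cell"][...],
            fixed=f["fixed"][...].astype(bool),
            expression=f["expression"][...],
            cell_tissue=f["cell_tissue"][...],
            cell_knot=f["cell_knot"][...].astype(bool),
            cell_phase=f["cell_phase"][...],
            cell_nodes=f["cell_nodes"][...],
            cell_EQS=f["cell_EQS"][...],
            adhesion=AdhesionTable(f["adhesion"][...]),
            time=float(f.attrs["time"]),
        )
        for name in _NODE_PARAMS:
            kwargs[name] = f[name][...]
    state = SimulationState(**kwargs)
    state.validate()
    return state


# ----------------------------------------------------------------------
# CSV dialect: one row per node, cell-level fields repeated on the
# cell's rows; adhesion matrix and clock in '#'-prefixed header lines.

def _save_csv(state: SimulationState, path) -> None:
    n = state.n_nodes
    coords = {ax: state.positions[:, d] for d, ax in enumerate("xyz"[: state.dim])}
    tissue = state.node_tissue()
    df = pd.DataFrame({
        "id": np.arange(n),
        "cell_id": state.node_cell,
        "tissue": [TISSUE_NAMES[t] for t in tissue],
        "role": [ROLE_NAMES[r] for r in state.role],
        **coords,
        "fixed": state.fixed.astype(int),
        "knot": state.cell_knot[state.node_cell].astype(int),
        "P_PHA": state.cell_phase[state.node_cell],
        "p_EQS": state.cell_EQS[state.node_cell],
        **{name: getattr(state, name) for name in _NODE_PARAMS},
    })
    header = (
        f"# toothmorph state v{_SCHEMA_VERSION}\n"
        f"# time: {state.time!r}\n"
        f"# dim: {state.dim}\n"
        f"# adhesion: {json.dumps(state.adhesion.b.tolist())}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def _load_csv(path) -> SimulationState:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line[1:].split(":", 1)
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    dim = int(meta.get("dim", 3))
    try:
        tissue_codes = np.array([TISSUE_NAMES.index(t) for t in df["tissue"]],
                                dtype=np.int8)
        role_codes = np.array([ROLE_NAMES.index(r) for r in df["role"]],
                              dtype=np.int8)
    except ValueError as exc:
        raise ValueError(f"unknown tissue or role label in {path}: {exc}") from None
    node_cell = df["cell_id"].to_numpy(dtype=np.int64)
    n_cells = node_cell.max() + 1
    cell_tissue = np.zeros(n_cells, dtype=np.int8)
    cell_tissue[node_cell] = tissue_codes
    cell_knot = np.zeros(n_cells, dtype=bool)
    cell_knot[node_cell] = df["knot"].to_numpy(dtype=bool)
    cell_phase = np.zeros(n_cells)
    cell_phase[node_cell] = df["P_PHA"].to_numpy()
    cell_EQS = np.full(n_cells, np.nan)
    cell_EQS[node_cell] = df["p_EQS"].to_numpy()
    cell_nodes = np.full((n_cells, 2), -1, dtype=np.int64)
    ids = df["id"].to_numpy(dtype=np.int64)
    for nid, cid, role in zip(ids, node_cell, role_codes):
        cell_nodes[cid, 1 if role == 2 else 0] = nid
    expression = np.zeros((len(df), 3))
    expression[np.arange(len(df)), tissue_codes] = 1.0
    state = SimulationState(
        positions=df[list("xyz"[:dim])].to_numpy(),
        role=role_codes,
        node_cell=node_cell,
        fixed=df["fixed"].to_numpy(dtype=bool),
        expression=expression,
        cell_tissue=cell_tissue,
        cell_knot=cell_knot,
        cell_phase=cell_phase,
        cell_nodes=cell_nodes,
        cell_EQS=cell_EQS,
        adhesion=AdhesionTable(np.array(json.loads(meta["adhesion"]))),
        time=float(meta.get("time", 0.0)),
        **{name: df[name].to_numpy() for name in _NODE_PARAMS},
    )
    state.validate()
    return state


def save_state(state: SimulationState, path) -> None:
    """Write a state snapshot; format chosen by extension (.h5/.hdf5 or
    .csv)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _save_h5(state, path)
    elif path.suffix.lower() == ".csv":
        _save_csv(state, path)
    else:
        raise ValueError(f"unsupported state format: {path.suffix!r}")


def load_state(path) -> SimulationState:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_h5(path)
    if path.suffix.lower() == ".csv":
        return _load_csv(path)
    raise ValueError(f"unsupported state format: {path.suffix!r}")


# ----------------------------------------------------------------------
# run configuration (versioned YAML schema)

def run_config_to_dict(config: RunConfig,
                       mech: MechanicalDefaults | None = None,
                       adhesion: AdhesionTable | None = None,
                       preset: str | None = None) -> dict:
    out = {
        "schema_version": _SCHEMA_VERSION,
        "growth": asdict(config.growth),
        "total_time": config.total_time,
        "seed": config.seed,
        "dt_growth": config.dt_growth,
        "mech_substeps": config.mech_substeps,
        "dt_mech": config.dt_mech,
        "snapshot_interval": config.snapshot_interval,
        "max_cells": config.max_cells,
    }
    if mech is not None:
        out["mechanics"] = asdict(mech)
    if adhesion is not None:
        out["adhesion"] = adhesion.b.tolist()
    if preset is not None:
        out["preset"] = preset
    return out


def run_config_from_dict(data: dict) -> tuple[RunConfig, MechanicalDefaults,
                                              AdhesionTable, str | None]:
    version = data.get("schema_version", _SCHEMA_VERSION)
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    growth = GrowthConfig(**data.get("growth", {}))
    if "seed" not in data:
        raise ValueError("config must carry an explicit seed")
    config = RunConfig(
        growth=growth,
        total_time=float(data["total_time"]),
        seed=int(data["seed"]),
        dt_growth=float(data.get("dt_growth", 0.25)),
        mech_substeps=int(data.get("mech_substeps", 20)),
        dt_mech=float(data.get("dt_mech", 0.08)),
        snapshot_interval=float(data.get("snapshot_interval", 2.0)),
        max_cells=int(data.get("max_cells", 20_000)),
    )
    mech = MechanicalDefaults(**data.get("mechanics", {}))
    adhesion = (AdhesionTable(np.array(data["adhesion"]))
                if "adhesion" in data else AdhesionTable())
    return config, mech, adhesion, data.get("preset")


def load_run_config(path):
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def save_run_config(path, config: RunConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(config, **kwargs), fh,
                       sort_keys=False)


# ----------------------------------------------------------------------
# manifest

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    started: str
    finished: str
    outputs: list[str]


def config_hash(config_dict: dict) -> str:
    canonical = json.dumps(config_dict, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(out_dir, config_dict: dict, seed: int,
                   outputs: list[str], started: float,
                   finished: float | None = None) -> RunManifest:
    from . import __version__

    finished = finished if finished is not None else _time.time()
    manifest = RunManifest(
        config_hash=config_hash(config_dict),
        seed=seed,
        software_version=__version__,
        started=_time.strftime("%Y-%m-%dT%H:%M:%S", _time.gmtime(started)),
        finished=_time.strftime("%Y-%m-%dT%H:%M:%S", _time.gmtime(finished)),
        outputs=[str(p) for p in outputs],
    )
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


# ----------------------------------------------------------------------
# ASCII PLY rods for external viewers

def stress_rods_to_ply(edges: pd.DataFrame, path, dim: int = 3) -> None:
    """Write stress rods (one line segment per contact) as ASCII PLY,
    with the stress value as a per-vertex quality channel."""
    axes = "xyz"[:dim]
    n = len(edges)
    half = 0.4
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {2 * n}\n")
        for ax in "xyz":
            fh.write(f"property float {ax}\n")
        fh.write("property float quality\n")
        fh.write(f"element edge {n}\n")
        fh.write("property int vertex1\nproperty int vertex2\nend_header\n")
        for _, row in edges.iterrows():
            mid = np.array([row.get(f"mid_{ax}", 0.0) for ax in "xyz"])
            d = np.array([row.get(f"dir_{ax}", 0.0) for ax in "xyz"])
            for sgn in (-1, 1):
                p = mid + sgn * half * d
                fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g} {row['stress']:.6g}\n")
        for e in range(n):
            fh.write(f"{2 * e} {2 * e + 1}\n")
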