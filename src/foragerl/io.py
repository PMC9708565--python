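"""Session CSV / RoiMatrix HDF5 readers and writers, configs, manifests.

Schemas
-------
Session CSV: one row per sample with columns ``t, x, y, reward_flag,
laser_flag, block_id``; flags are 1 on the sample nearest the event.

RoiMatrix HDF5: datasets ``/dff`` and ``/spikes`` (ROI x frame),
``/frame_times`` (seconds), root attribute ``frame_rate``; optional
``/roi_footprints``.

Run manifests are JSON files embedding the seed and a hash of the
configuration that produced an artifact, so any output can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import PositionTrace
from .neural import RoiMatrix

__all__ = [
    "save_session",
    "load_session",
    "save_roi_matrix",
    "load_roi_matrix",
    "save_sim_result",
    "load_config",
    "save_config",
    "write_manifest",
    "SchemaError",
    "DataError",
]

REQUIRED_COLUMNS = ("t", "x", "y", "reward_flag", "laser_flag", "block_id")


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


class DataError(ValueError):
    """A file conforms to the schema but carries invalid data."""


def save_session(
    path,
    trace: PositionTrace,
    reward_times: np.ndarray | None = None,
    laser_times: np.ndarray | None = None,
    block_id: np.ndarray | int = 1,
) -> None:
    """Write a behavioral session to the documented CSV schema."""
    n = len(trace.t)
    reward_flag = np.zeros(n, dtype=int)
    laser_flag = np.zeros(n, dtype=int)
    for times, flag in ((reward_times, reward_flag), (laser_times, laser_flag)):
        if times is not None and len(times):
            idx = np.searchsorted(trace.t, np.asarray(times))
            flag[np.clip(idx, 0, n - 1)] = 1
    if np.isscalar(block_id):
        block_id = np.full(n, block_id, dtype=int)
    pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.x,
            "y": trace.y,
            "reward_flag": reward_flag,
            "laser_flag": laser_flag,
            "block_id": np.asarray(block_id, dtype=int),
        }
    ).to_csv(path, index=False)


def load_session(path) -> tuple[PositionTrace, dict]:
    """Read a session CSV; returns (trace, events).

    Events carry ``reward_times``, ``laser_times`` and the per-sample
    ``block_id``.  Raises :class:`SchemaError` for missing columns and
    :class:`DataError` for non-monotone time.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"session file {path} missing column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise DataError(f"session file {path}: time not strictly increasing")
    trace = PositionTrace(
        t, df["x"].to_numpy(float), df["y"].to_numpy(float)
    )
    events = {
        "reward_times": t[df["reward_flag"].to_numpy() > 0],
        "laser_times": t[df["laser_flag"].to_numpy() > 0],
        "block_id": df["block_id"].to_numpy(int),
    }
    return trace, events


def save_roi_matrix(path, roi: RoiMatrix) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("dff", data=roi.dff)
        fh.create_dataset("spikes", data=roi.spikes)
        fh.create_dataset("frame_times", data=roi.frame_times)
        fh.attrs["frame_rate"] = roi.frame_rate
        if roi.roi_footprints is not None:
            fh.create_dataset("roi_footprints", data=roi.roi_footprints)


def load_roi_matrix(path) -> RoiMatrix:
    with h5py.File(path, "r") as fh:
        for name in ("dff", "spikes", "frame_times"):
            if name not in fh:
                raise SchemaError(f"{path} missing dataset /{name}")
        dff = fh["dff"][()]
        spikes = fh["spikes"][()]
        if dff.shape != spikes.shape:
            raise DataError(
                f"{path}: /dff shape {dff.shape} != /spikes shape {spikes.shape}"
            )
        return RoiMatrix(
            dff=dff,
            spikes=spikes,
            frame_rate=float(fh.attrs["frame_rate"]),
            frame_times=fh["frame_times"][()],
            roi_footprints=(
                fh["roi_footprints"][()] if "roi_footprints" in fh else None
            ),
        )


def save_sim_result(csv_path, h5_path, sim) -> None:
    """Write a simulated session: per-trial CSV plus trajectory HDF5.

    The CSV has one row per trial (index, block, executed gain and heading,
    max amplitude, rewarded, perturbed, initiation latency); the HDF5 file
    stores each trial's full trajectory under ``/trajectories/NNN`` and the
    session configuration as a YAML text attribute.
    """
    rows = pd.DataFrame(
        {
            "index": [t.index for t in sim.trials],
            "block": [t.block_target for t in sim.trials],
            "a": [t.a for t in sim.trials],
            "omega": [t.omega for t in sim.trials],
            "max_amplitude": [t.max_amplitude for t in sim.trials],
            "rewarded": [int(t.rewarded) for t in sim.trials],
            "perturbed": [int(t.perturbed) for t in sim.trials],
            "initiation_latency": [
                np.nan if t.initiation_latency is None else t.initiation_latency
                for t in sim.trials
            ],
        }
    )
    rows.to_csv(csv_path, index=False)
    with h5py.File(h5_path, "w") as fh:
        grp = fh.create_group("trajectories")
        for t in sim.trials:
            if t.trajectory is not None:
                grp.create_dataset(f"{t.index:04d}", data=t.trajectory)
        fh.attrs["config_yaml"] = yaml.safe_dump(_plain(sim.config))
        if sim.seed is not None:
            fh.attrs["seed"] = sim.seed


def save_config(path, config) -> None:
    """Serialise a (nested-dataclass or dict) configuration to YAML."""
    obj = asdict(config) if is_dataclass(config) else config
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, frozenset, set)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    blob = json.dumps(
        _plain(asdict(config) if is_dataclass(config) else config),
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path, config, seed, outputs: list[str] | None = None) -> None:
    """JSON run manifest: inputs, parameters, config hash and seed."""
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _plain(asdict(config) if is_dataclass(config) else config),
        "outputs": outputs or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
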