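"""File formats: spike rasters, positions, parameter tables, correlation
matrices, run manifests.

Plain-text first (TSV/JSON/YAML); HDF5 bundles for whole spike-train sets
where a single binary artifact is preferable.  An optional reader for
MEA recordings stored in MATLAB containers is import-guarded and never
required by the synthetic pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .params import NeuronParams
from .synth import SpikeTrainSet

__all__ = [
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_positions_tsv",
    "read_positions_tsv",
    "write_spike_train_set_h5",
    "read_spike_train_set_h5",
    "write_params_json",
    "read_params_json",
    "write_params_yaml",
    "read_params_yaml",
    "write_matrix_tsv",
    "write_manifest",
    "write_voltage_tsv",
    "load_mea_mat",
]


def write_spikes_tsv(path, train_set: SpikeTrainSet) -> None:
    """Two-column (unit id, spike time s) table."""
    with open(path, "w") as f:
        f.write("# unit\ttime_s\n")
        for i, train in enumerate(train_set.spike_times):
            uid = int(train_set.unit_ids[i])
            for t in train:
                f.write(f"{uid}\t{t:.6f}\n")


def read_spikes_tsv(path, positions: np.ndarray, duration_s: float) -> SpikeTrainSet:
    data = np.loadtxt(path, comments="#", ndmin=2)
    n = positions.shape[0]
    trains = []
    for i in range(n):
        sel = data[:, 0].astype(int) == i if data.size else np.zeros(0, bool)
        trains.append(np.sort(data[sel, 1]) if data.size else np.zeros(0))
    return SpikeTrainSet(
        unit_ids=np.arange(n), spike_times=trains, positions=positions,
        duration_s=duration_s, provenance="file",
    )


def write_positions_tsv(path, positions: np.ndarray) -> None:
    np.savetxt(path, positions, delimiter="\t", header="x\ty", comments="# ")


def read_positions_tsv(path) -> np.ndarray:
    return np.loadtxt(path, comments="#", ndmin=2)


def write_spike_train_set_h5(path, ts: SpikeTrainSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = ts.duration_s
        f.attrs["provenance"] = ts.provenance
        f.create_dataset("unit_ids", data=ts.unit_ids)
        f.create_dataset("positions", data=ts.positions)
        flat = np.concatenate(ts.spike_times) if ts.n_units else np.zeros(0)
        lens = np.array([t.size for t in ts.spike_times], dtype=np.int64)
        f.create_dataset("spike_times_flat", data=flat)
        f.create_dataset("train_lengths", data=lens)


def read_spike_train_set_h5(path) -> SpikeTrainSet:
    import h5py

    with h5py.File(path, "r") as f:
        flat = f["spike_times_flat"][:]
        lens = f["train_lengths"][:]
        offs = np.concatenate([[0], np.cumsum(lens)])
        trains = [flat[offs[i]:offs[i + 1]] for i in range(lens.size)]
        return SpikeTrainSet(
            unit_ids=f["unit_ids"][:],
            spike_times=trains,
            positions=f["positions"][:],
            duration_s=float(f.attrs["duration_s"]),
            provenance=str(f.attrs["provenance"]),
        )


def write_params_json(path, params: NeuronParams) -> None:
    Path(path).write_text(params.to_json())


def read_params_json(path) -> NeuronParams:
    return NeuronParams.from_json(Path(path).read_text())


def write_params_yaml(path, params: NeuronParams) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def read_params_yaml(path) -> NeuronParams:
    return NeuronParams.from_dict(yaml.safe_load(Path(path).read_text()))


def write_matrix_tsv(path, matrix: np.ndarray, header: str = "") -> None:
    np.savetxt(path, matrix, delimiter="\t", header=header, comments="# ")


def write_voltage_tsv(path, t_ms: np.ndarray, v_mV: np.ndarray) -> None:
    np.savetxt(
        path, np.column_stack([t_ms, v_mV]), delimiter="\t",
        header="t_ms\tv_mV", comments="# ",
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_manifest(path, manifest: dict) -> None:
    """JSON manifest of a run: all seeds and constants, numpy-safe."""
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=1, sort_keys=True))


def load_mea_mat(path) -> SpikeTrainSet:
    """Optional loader for MEA recordings stored in common MATLAB
    container layouts (variables ``spiketimes`` or per-channel cell
    arrays plus electrode ``x``/``y``).  Never required by the synthetic
    pipeline; raises ImportError cleanly if scipy.io cannot read it."""
    from scipy.io import loadmat  # import guard: optional path

    raw = loadmat(path, squeeze_me=True)
    keys = {k.lower(): k for k in raw if not k.startswith("__")}
    if "spiketimes" not in keys:
        raise ValueError("unrecognized container: no 'spiketimes' variable")
    spikes = raw[keys["spiketimes"]]
    trains = [np.atleast_1d(np.sort(np.asarray(t, dtype=float).ravel()))
              for t in np.atleast_1d(spikes)]
    if "x" in keys and "y" in keys:
        pos = np.column_stack([
            np.asarray(raw[keys["x"]], float).ravel(),
            np.asarray(raw[keys["y"]], float).ravel(),
        ])
    else:
        side = int(np.ceil(np.sqrt(len(trains))))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel()])[: len(trains)].astype(float)
    duration = max((t[-1] for t in trains if t.size), default=0.0)
    return SpikeTrainSet(
        unit_ids=np.arange(len(trains)), spike_times=trains,
        positions=pos, duration_s=float(duration), provenance="file",
    )
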