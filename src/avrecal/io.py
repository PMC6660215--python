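"""On-disk formats: TSV trial/bias tables, JSON results, HDF5 epoch and map
containers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import TRIAL_COLUMNS, SourceEpochs, SourceGrid


def write_trials_tsv(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_trials_tsv(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table {path} missing columns: {missing}")
    bad_av = trials[(trials["type"] == "AV") & (trials["A_loc"].isna() | trials["V_loc"].isna())]
    if len(bad_av):
        raise DataError(f"{len(bad_av)} AV trials lack A_loc/V_loc in {path}")
    bad_a = trials[(trials["type"] == "A") & trials["A_loc"].isna()]
    if len(bad_a):
        raise DataError(f"{len(bad_a)} A trials lack A_loc in {path}")
    return trials


def write_epochs_h5(epochs: SourceEpochs, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("voxel_coords_mm", data=epochs.grid.coords)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.attrs["grid_shape"] = epochs.grid.shape
        f.attrs["spacing_mm"] = epochs.grid.spacing
        if epochs.subject is not None:
            f.attrs["subject"] = epochs.subject
    return path


def read_epochs_h5(path: str | Path) -> SourceEpochs:
    with h5py.File(path, "r") as f:
        grid = SourceGrid(tuple(int(n) for n in f.attrs["grid_shape"]), float(f.attrs["spacing_mm"]))
        epochs = SourceEpochs(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            grid=grid,
            trial_index=f["trial_index"][()],
            subject=int(f.attrs["subject"]) if "subject" in f.attrs else None,
        )
    return epochs


def write_arrays_h5(path: str | Path, arrays: dict[str, np.ndarray], attrs: dict | None = None) -> Path:
    """Generic container for named numeric arrays (AUC maps, beta maps,
    projections) with axis metadata in attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr, compression="gzip", compression_opts=1)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
    return path


def read_arrays_h5(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as f:
        arrays = {name: f[name][()] for name in f}
        attrs = dict(f.attrs)
    return arrays, attrs


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
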