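"""Array I/O: recordings as headered CSV, NPZ or HDF5, results as JSON.

CSV files are comma-separated with a header row and '.' decimals. EMG files
carry columns ``ch1..ch32``; angle files carry ``WFWE,PS,HGHO``. NPZ/HDF5
round trips are value-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .containers import AngleRecording, EMGRecording, JOINT_NAMES
from .errors import IOFormatError

Recording = Union[EMGRecording, AngleRecording]

EMG_RATE_HZ = 500.0
ANGLE_RATE_HZ = 120.0


def _expected_columns(kind: str):
    if kind == "emg":
        return [f"ch{i}" for i in range(1, 33)]
    if kind == "angles":
        return list(JOINT_NAMES)
    raise IOFormatError(f"unknown recording kind {kind!r}")


def _build(kind: str, samples: np.ndarray, fs: float, trial_id=None, session_id=None):
    if kind == "emg":
        return EMGRecording(samples=samples, fs=fs, trial_id=trial_id, session_id=session_id)
    return AngleRecording(samples=samples, fs=fs, trial_id=trial_id, session_id=session_id)


def read_recording(path, kind: str, fs: float = None) -> Recording:
    """Load a recording; format chosen by extension (.csv, .npz, .h5/.hdf5).

    ``fs`` overrides the default rate for CSV files (which store no
    metadata); NPZ/HDF5 carry their rate.
    """
    path = Path(path)
    cols = _expected_columns(kind)
    default_fs = EMG_RATE_HZ if kind == "emg" else ANGLE_RATE_HZ
    if path.suffix == ".csv":
        frame = pd.read_csv(path)
        if list(frame.columns) != cols:
            raise IOFormatError(
                f"{path}: expected {len(cols)} columns {cols[0]}..{cols[-1]}, "
                f"got {len(frame.columns)}: {list(frame.columns)[:5]}..."
            )
        samples = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(samples)):
            raise IOFormatError(f"{path}: non-finite values")
        return _build(kind, samples, fs or default_fs)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            samples = data["samples"]
            file_fs = float(data["fs"]) if "fs" in data else default_fs
        return _build(kind, samples, fs or file_fs)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            samples = fh["samples"][()]
            file_fs = float(fh["samples"].attrs.get("fs", default_fs))
        return _build(kind, samples, fs or file_fs)
    raise IOFormatError(f"{path}: unsupported format {path.suffix!r}")


def write_recording(rec: Recording, path, force: bool = False) -> None:
    """Write a recording; format chosen by extension; round-trips exactly
    for NPZ/HDF5. Refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    kind = "emg" if isinstance(rec, EMGRecording) else "angles"
    cols = _expected_columns(kind)
    if path.suffix == ".csv":
        pd.DataFrame(rec.samples, columns=cols).to_csv(path, index=False)
    elif path.suffix == ".npz":
        np.savez(path, samples=rec.samples, fs=np.asarray(rec.fs))
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("samples", data=rec.samples)
            ds.attrs["fs"] = rec.fs
    else:
        raise IOFormatError(f"{path}: unsupported format {path.suffix!r}")


def save_json(obj: dict, path, force: bool = True) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
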