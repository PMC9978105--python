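"""Epoch-store readers and writers.

Two dialects of the same schema:

* **HDF5 file** (path ending in ``.h5``/``.hdf5``): one float64 dataset
  ``data`` of shape ``(n_trials, n_samples, n_channels)``, string datasets
  ``subject_id``/``label``, integer ``trial_id``, and file attributes
  ``channel_names`` and ``sfreq``.  Written with ``track_times=False`` so
  identical datasets produce byte-identical files.
* **CSV directory** (any other path, treated as a directory): a
  ``manifest.csv`` (trial order, subject, label, file name), a ``meta.json``
  (channel names, sampling rate) and one wide-format CSV per trial
  (``n_samples`` rows, one column per channel).  Intended for eyeballing;
  round-trips within float round-off.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import EpochDataset, SchemaError

_STR = h5py.string_dtype(encoding="utf-8")


def _is_hdf5(path) -> bool:
    return str(path).endswith((".h5", ".hdf5"))


def write_epochs(dataset: EpochDataset, path) -> None:
    """Write a dataset in the dialect selected by the path suffix."""
    path = Path(path)
    if _is_hdf5(path):
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w", track_order=True) as f:
            f.create_dataset("data", data=dataset.data, track_times=False)
            f.create_dataset("subject_id", data=dataset.subject_ids.astype(object),
                             dtype=_STR, track_times=False)
            f.create_dataset("label", data=dataset.labels.astype(object),
                             dtype=_STR, track_times=False)
            f.create_dataset("trial_id", data=dataset.trial_ids,
                             track_times=False)
            f.attrs["channel_names"] = np.asarray(dataset.channel_names,
                                                  dtype=object)
            f.attrs["sfreq"] = float(dataset.sfreq)
        return
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        fname = f"trial_{i:05d}.csv"
        # default float formatting is the shortest round-trippable repr
        pd.DataFrame(dataset.data[i], columns=dataset.channel_names).to_csv(
            path / fname, index=False)
        rows.append({"trial_id": int(dataset.trial_ids[i]),
                     "subject_id": dataset.subject_ids[i],
                     "label": dataset.labels[i], "file": fname})
    pd.DataFrame(rows, columns=["trial_id", "subject_id", "label", "file"]) \
        .to_csv(path / "manifest.csv", index=False)
    (path / "meta.json").write_text(json.dumps(
        {"channel_names": dataset.channel_names, "sfreq": dataset.sfreq},
        indent=1))


def read_epochs(path) -> EpochDataset:
    """Read either dialect back into an :class:`EpochDataset`.

    Schema violations (missing fields, shape mismatches, unknown labels)
    raise :class:`~erpdtw.data.SchemaError` naming the offending field.
    """
    path = Path(path)
    if _is_hdf5(path):
        if not path.exists():
            raise SchemaError(f"no such epoch store: {path}")
        with h5py.File(path, "r") as f:
            for key in ("data", "subject_id", "label", "trial_id"):
                if key not in f:
                    raise SchemaError(f"epoch store {path} is missing '{key}'")
            if "channel_names" not in f.attrs or "sfreq" not in f.attrs:
                raise SchemaError(
                    f"epoch store {path} is missing channel_names/sfreq attributes")
            data = f["data"][...]
            subjects = f["subject_id"].asstr()[...]
            labels = f["label"].asstr()[...]
            trial_ids = f["trial_id"][...]
            channels = [str(c) for c in f.attrs["channel_names"]]
            sfreq = float(f.attrs["sfreq"])
    else:
        manifest_path = path / "manifest.csv"
        meta_path = path / "meta.json"
        if not manifest_path.exists() or not meta_path.exists():
            raise SchemaError(f"{path} is not a CSV epoch store "
                              "(manifest.csv/meta.json missing)")
        manifest = pd.read_csv(manifest_path, dtype={"subject_id": str,
                                                     "label": str})
        meta = json.loads(meta_path.read_text())
        channels = [str(c) for c in meta["channel_names"]]
        sfreq = float(meta["sfreq"])
        mats = []
        for _, row in manifest.iterrows():
            df = pd.read_csv(path / row["file"], float_precision="round_trip")
            if list(df.columns) != channels:
                raise SchemaError(
                    f"trial file {row['file']}: columns {list(df.columns)} "
                    f"do not match channel names")
            mats.append(df.to_numpy(dtype=np.float64))
        data = (np.stack(mats) if mats
                else np.empty((0, 0, len(channels))))
        subjects = manifest["subject_id"].to_numpy(dtype=str)
        labels = manifest["label"].to_numpy(dtype=str)
        trial_ids = manifest["trial_id"].to_numpy(dtype=np.int64)

    if data.ndim != 3:
        raise SchemaError(f"data must be 3-D, got shape {data.shape}")
    if len(data) and data.shape[2] != len(channels):
        raise SchemaError(
            f"data has {data.shape[2]} channels but {len(channels)} "
            f"channel names are declared")
    try:
        return EpochDataset(data=data, subject_ids=subjects, labels=labels,
                            trial_ids=trial_ids, channel_names=channels,
                            sfreq=sfreq)
    except SchemaError:
        raise
    except ValueError as err:
        raise SchemaError(str(err)) from err
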