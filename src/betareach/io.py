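"""File formats: HDF5 epochs, CSV kinematics, TSV layouts and report tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import KinematicRecord, records_table
from .tfr import ChannelLayout, EEGEpochs

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_kinematics",
    "load_kinematics",
    "save_beta_timecourse",
    "save_json",
    "load_json",
]


def save_epochs(epochs: EEGEpochs, path) -> None:
    """Write epochs to HDF5: /epochs (trials x channels x samples), /times,
    /layout and /metadata tables, fs and alignment as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.attrs["fs"] = epochs.fs
        f.attrs["alignment"] = epochs.alignment
        f.attrs["info"] = json.dumps(epochs.info)
        lay = f.create_group("layout")
        for col in ("channel", "x", "y"):
            lay.create_dataset(col, data=epochs.layout.table[col].to_numpy())
        lay.create_dataset(
            "region",
            data=np.array(epochs.layout.table["region"], dtype="S16"),
        )
        if epochs.metadata is not None:
            md = f.create_group("metadata")
            for col in epochs.metadata.columns:
                vals = epochs.metadata[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S32")
                md.create_dataset(col, data=vals)


def load_epochs(path) -> EEGEpochs:
    with h5py.File(path, "r") as f:
        layout = ChannelLayout(
            pd.DataFrame(
                {
                    "channel": f["layout/channel"][()],
                    "x": f["layout/x"][()],
                    "y": f["layout/y"][()],
                    "region": [s.decode() for s in f["layout/region"][()]],
                }
            )
        )
        metadata = None
        if "metadata" in f:
            cols = {}
            for col in f["metadata"]:
                v = f["metadata"][col][()]
                if v.dtype.kind == "S":
                    v = np.array([s.decode() for s in v])
                cols[col] = v
            metadata = pd.DataFrame(cols)
        return EEGEpochs(
            data=f["epochs"][()],
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            layout=layout,
            alignment=str(f.attrs["alignment"]),
            metadata=metadata,
            info=json.loads(f.attrs.get("info", "{}")),
        )


def save_kinematics(records, path) -> None:
    records_table(records).to_csv(path, index=False)


def load_kinematics(path) -> list[KinematicRecord]:
    df = pd.read_csv(path)
    return [KinematicRecord(**row) for row in df.to_dict("records")]


def save_beta_timecourse(tc, path, channels=None) -> None:
    """Tidy TSV export of a band-power time course: channel, time_s, value."""
    nc, nt = tc.values.shape
    ch = np.arange(nc) if channels is None else np.asarray(channels)
    pd.DataFrame(
        {
            "channel": np.repeat(ch, nt),
            "time_s": np.tile(tc.times, nc),
            "value": tc.values.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
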