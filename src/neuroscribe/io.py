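"""HDF5 container I/O for recordings, feature matrices, template libraries
and decoder checkpoints, plus small CSV exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .neural_features import FeatureMatrix, RawRecording
from .recognition import TemplateLibrary

__all__ = [
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
    "save_library",
    "load_library",
    "save_checkpoint",
    "load_checkpoint",
    "features_to_csv",
    "path_to_csv",
]


def save_recording(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.create_dataset("channel_ids", data=np.asarray(rec.channel_ids))


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_ids=list(f["channel_ids"][()]),
        )


def save_features(fm: FeatureMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        f.attrs.update(
            {"kind": fm.kind, "bin_ms": fm.bin_ms, "step_ms": fm.step_ms,
             "lag_ms": fm.lag_ms}
        )


def load_features(path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            values=f["values"][()],
            kind=str(f.attrs["kind"]),
            bin_ms=float(f.attrs["bin_ms"]),
            step_ms=float(f.attrs["step_ms"]),
            lag_ms=float(f.attrs["lag_ms"]),
        )


def save_library(lib: TemplateLibrary, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("entries")
        for cid, tmpl in lib.entries.items():
            grp.create_dataset(cid, data=tmpl)
        f.attrs["provenance"] = json.dumps(lib.provenance)


def load_library(path) -> TemplateLibrary:
    with h5py.File(path, "r") as f:
        entries = {cid: f["entries"][cid][()] for cid in f["entries"]}
        prov = json.loads(f.attrs.get("provenance", "{}"))
    return TemplateLibrary(entries=entries, provenance=prov)


def save_checkpoint(params: dict, meta: dict, path) -> None:
    """Decoder weights plus a JSON manifest (seed, config, loss curve)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for k, v in params.items():
            grp.create_dataset(k, data=np.asarray(v))
        f.attrs["meta"] = json.dumps(meta)


def load_checkpoint(path) -> tuple[dict, dict]:
    with h5py.File(path, "r") as f:
        params = {k: f["params"][k][()] for k in f["params"]}
        meta = json.loads(f.attrs["meta"])
    return params, meta


def features_to_csv(fm: FeatureMatrix, path) -> None:
    pd.DataFrame(fm.values).to_csv(path, index_label="channel")


def path_to_csv(path_cells, out_path) -> None:
    pd.DataFrame(path_cells, columns=["i", "j"]).to_csv(out_path, index=False)
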