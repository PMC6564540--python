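"""Readers and writers for the on-disk artifact formats.

Trial sets travel in two dialects: a plain-text container (one JSON
metadata file plus per-trial TSV matrices, rows = channels, columns =
samples, no header) and a single HDF5 file.  Decision and session logs are
JSON lines.  Code sets, template banks and calibration results serialize
through their own ``to_json``/``save`` methods; thin wrappers live here so
the CLI has one import surface.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .stimcodes import CodeSet
from .synth import TrialSet

__all__ = [
    "save_trialset_tsv",
    "load_trialset_tsv",
    "save_trialset_hdf5",
    "load_trialset_hdf5",
    "write_jsonl",
    "read_jsonl",
]


def _trialset_meta(ts: TrialSet) -> dict:
    meta = {
        "sampling_rate": ts.sampling_rate,
        "n_channels": ts.n_channels,
        "paradigm": ts.paradigm,
        "labels": ts.labels.tolist(),
        "blocks": ts.blocks.tolist(),
        "n_trials": ts.n_trials,
        "meta": ts.meta,
    }
    if ts.codeset is not None:
        meta["codeset"] = ts.codeset.to_dict()
    return meta


def save_trialset_tsv(ts: TrialSet, directory) -> None:
    """Text dialect: ``meta.json`` + ``trial_0000.tsv`` ... (channels x
    samples, tab-separated)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "meta.json", "w") as fh:
        json.dump(_trialset_meta(ts), fh, indent=1, sort_keys=True)
    for i, t in enumerate(ts.trials):
        np.savetxt(d / f"trial_{i:04d}.tsv", t, delimiter="\t")


def load_trialset_tsv(directory) -> TrialSet:
    d = Path(directory)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    trials = [
        np.loadtxt(d / f"trial_{i:04d}.tsv", delimiter="\t", ndmin=2)
        for i in range(meta["n_trials"])
    ]
    return TrialSet(
        trials=trials,
        labels=np.asarray(meta["labels"]),
        blocks=np.asarray(meta["blocks"]),
        sampling_rate=meta["sampling_rate"],
        paradigm=meta["paradigm"],
        codeset=CodeSet.from_dict(meta["codeset"]) if "codeset" in meta else None,
        meta=meta.get("meta", {}),
    )


def save_trialset_hdf5(ts: TrialSet, path) -> None:
    """HDF5 dialect: one ``trials`` dataset (n_trials, m, n_t) plus label
    and block vectors; metadata as a JSON attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=np.stack(ts.trials))
        f.create_dataset("labels", data=ts.labels)
        f.create_dataset("blocks", data=ts.blocks)
        f.attrs["meta"] = json.dumps(_trialset_meta(ts), sort_keys=True)


def load_trialset_hdf5(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        trials = [np.array(t) for t in f["trials"]]
        labels = np.array(f["labels"])
        blocks = np.array(f["blocks"])
        meta = json.loads(f.attrs["meta"])
    return TrialSet(
        trials=trials,
        labels=labels,
        blocks=blocks,
        sampling_rate=meta["sampling_rate"],
        paradigm=meta["paradigm"],
        codeset=CodeSet.from_dict(meta["codeset"]) if "codeset" in meta else None,
        meta=meta.get("meta", {}),
    )


def write_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path) -> list:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
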