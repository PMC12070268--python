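"""Serialisation of the pipeline's containers.

Epochs are written as a NumPy ``.npz`` holding the voltage array plus a
JSON sidecar with channel names and positions, sampling rate and
condition labels.  Behavioural tables travel as TSV with fixed column
names (subject, group, overlap, hit_rate, rt_ms, fa_rate); cluster
results as JSON/TSV summaries.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clusterperm import ClusterSet
from .synthgen import Epochs, SensorArray

BEHAVIOR_COLUMNS = ["subject", "group", "overlap", "hit_rate", "rt_ms", "fa_rate"]


def save_epochs(epochs: Epochs, path) -> Path:
    """Write epochs to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data)
    sidecar = dict(
        subject_id=epochs.subject_id,
        group=epochs.group,
        condition=epochs.condition,
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        channels=list(epochs.array.names),
        positions=epochs.array.positions.tolist(),
        units="uV",
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_epochs(path) -> Epochs:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))["data"]
    array = SensorArray(names=meta["channels"], positions=np.array(meta["positions"]))
    return Epochs(
        subject_id=meta["subject_id"], group=meta["group"],
        condition=meta["condition"], data=data,
        sfreq=meta["sfreq"], tmin=meta["tmin"], array=array,
    )


def save_behavior(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[BEHAVIOR_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def load_behavior(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behavioural table missing columns {sorted(missing)}")
    return table


def save_source_map(values, positions_mm, path, band=None, condition=None) -> Path:
    """Source power/contrast map as TSV (voxel index, xyz in mm, value)
    with a JSON metadata sidecar."""
    path = Path(path)
    values = np.asarray(values, float)
    positions_mm = np.asarray(positions_mm, float)
    table = pd.DataFrame(
        dict(voxel=np.arange(len(values)),
             x_mm=positions_mm[:, 0], y_mm=positions_mm[:, 1],
             z_mm=positions_mm[:, 2], value=values)
    )
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    meta = dict(band=list(band) if band else None, condition=condition,
                n_voxels=int(len(values)))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".tsv")


def load_source_map(path):
    path = Path(path)
    table = pd.read_csv(path.with_suffix(".tsv"), sep="\t")
    positions = table[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return table["value"].to_numpy(), positions


def save_clusters(cluster_set: ClusterSet, path) -> Path:
    """ClusterSet as JSON (members, sign, T_sum, p) plus a TSV summary."""
    path = Path(path)
    payload = dict(
        design=cluster_set.design,
        threshold=cluster_set.threshold,
        n_randomizations=cluster_set.n_randomizations,
        alpha=cluster_set.alpha,
        clusters=cluster_set.to_records(),
    )
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    rows = [
        dict(cluster=i, sign=c.sign, size=len(c.nodes), t_sum=c.t_sum, p=c.p)
        for i, c in enumerate(cluster_set.clusters)
    ]
    pd.DataFrame(rows, columns=["cluster", "sign", "size", "t_sum", "p"]).to_csv(
        path.with_suffix(".tsv"), sep="\t", index=False
    )
    return path.with_suffix(".json")
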