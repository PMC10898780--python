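"""Delimited-text I/O for BOLD matrices, connectomes and overlap tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hopf import StructuralConnectome
from .phases import BoldTimeseries

__all__ = [
    "read_bold",
    "write_bold",
    "read_connectome",
    "write_connectome",
    "read_overlap_table",
]


def read_bold(path, tr: float | None = None) -> BoldTimeseries:
    """Read a nodes x volumes matrix; TR from the sidecar JSON unless given."""
    path = Path(path)
    if tr is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"no TR given and no sidecar {sidecar.name}")
        tr = float(json.loads(sidecar.read_text())["tr"])
    values = np.loadtxt(path, delimiter="\t")
    return BoldTimeseries(values=values, tr=tr)


def write_bold(ts: BoldTimeseries, path) -> None:
    path = Path(path)
    np.savetxt(path, ts.values, delimiter="\t")
    path.with_suffix(".json").write_text(json.dumps({"tr": ts.tr}))


def read_connectome(path) -> StructuralConnectome:
    """Square matrix plus sidecar JSON (provenance, lambda_c, distances file)."""
    path = Path(path)
    C = np.loadtxt(path, delimiter="\t")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    distances = None
    if meta.get("distances_file"):
        distances = np.loadtxt(path.parent / meta["distances_file"], delimiter="\t")
    return StructuralConnectome(
        C=C,
        provenance=meta.get("provenance", "external"),
        lambda_c=meta.get("lambda_c"),
        distances=distances,
    )


def write_connectome(conn: StructuralConnectome, path) -> None:
    path = Path(path)
    np.savetxt(path, conn.C, delimiter="\t")
    meta = {"provenance": conn.provenance, "lambda_c": conn.lambda_c}
    if conn.distances is not None:
        dfile = path.stem + "_distances.tsv"
        np.savetxt(path.parent / dfile, conn.distances, delimiter="\t")
        meta["distances_file"] = dfile
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_overlap_table(path) -> pd.DataFrame:
    """Long (patient, node, fraction) or wide patients x nodes table."""
    df = pd.read_csv(path, sep="\t")
    if {"patient", "node", "fraction"} <= set(df.columns):
        return df.pivot(index="patient", columns="node", values="fraction").fillna(0.0)
    return df.set_index(df.columns[0]) if df.dtypes.iloc[0] == object else df
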