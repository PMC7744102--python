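"""File readers and writers: SWC skeletons, synapse/eye-center/trace CSVs.

CSV dialect throughout: comma-separated, UTF-8, '.' decimal, header
mandatory.  SWC is the standard 7-column dialect (id, type, x, y, z,
radius, parent; parent -1 for the root), coordinates in nm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .geometry import NODE_COLUMNS, Skeleton

__all__ = [
    "read_swc",
    "write_swc",
    "read_synapses",
    "write_synapses",
    "read_eye_centers",
    "write_eye_centers",
    "read_traces",
    "write_traces",
]

SWC_LABELS = {0: "unlabeled", 1: "soma", 2: "axon", 3: "dendrite"}
SWC_TYPES = {v: k for k, v in SWC_LABELS.items()}
SYNAPSE_COLUMNS = ["pre_id", "post_id", "x_nm", "y_nm", "z_nm"]


def read_swc(path, neuron_id=None) -> Skeleton:
    """Read one neuron skeleton from an SWC file.

    Structure types 1/2/3 map to soma/axon/dendrite labels; anything
    else is 'unlabeled'.  Cycles, multiple roots and dangling parents
    are rejected by skeleton validation.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, radius = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
            rows.append((nid, parent, x, y, z, radius, SWC_LABELS.get(stype, "unlabeled")))
    if not rows:
        raise FormatError(f"{path}: no nodes")
    df = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return Skeleton(neuron_id if neuron_id is not None else path.stem, df)


def write_swc(skel: Skeleton, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for _, r in skel.nodes.iterrows():
            fh.write(
                f"{int(r.node_id)} {SWC_TYPES.get(r.label, 0)} "
                f"{r.x:.3f} {r.y:.3f} {r.z:.3f} {r.radius:.3f} {int(r.parent_id)}\n"
            )


def read_synapses(path) -> pd.DataFrame:
    """Synapse table: pre_id, post_id (may be empty for bare presynapse
    sites), x_nm, y_nm, z_nm.  Duplicated rows are preserved — polyadic
    synapses are real.  Returns columns pre_id, post_id, x, y, z."""
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("x_nm", "y_nm", "z_nm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric {col} at data line {int(bad.idxmax()) + 2}"
            )
    out = df.rename(columns={"x_nm": "x", "y_nm": "y", "z_nm": "z"})
    out[["x", "y", "z"]] = out[["x", "y", "z"]].astype(float)
    return out[["pre_id", "post_id", "x", "y", "z"]]


def write_synapses(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"x": "x_nm", "y": "y_nm", "z": "z_nm"})
    out[SYNAPSE_COLUMNS].to_csv(path, index=False)


def read_eye_centers(path) -> dict:
    df = pd.read_csv(path, dtype={"neuron_id": str})
    for col in ("neuron_id", "lon_deg", "lat_deg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return {r.neuron_id: (float(r.lon_deg), float(r.lat_deg)) for r in df.itertuples()}


def write_eye_centers(eye_centers: dict, path) -> None:
    rows = [(nid, lon, lat) for nid, (lon, lat) in sorted(eye_centers.items())]
    pd.DataFrame(rows, columns=["neuron_id", "lon_deg", "lat_deg"]).to_csv(path, index=False)


def read_traces(path) -> dict:
    """Calcium traces keyed by stimulus id, from (stim_id, frame, F) rows."""
    df = pd.read_csv(path, dtype={"stim_id": str})
    for col in ("stim_id", "frame", "F"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return {
        sid: grp.sort_values("frame")["F"].to_numpy(dtype=float)
        for sid, grp in df.groupby("stim_id")
    }


def write_traces(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
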