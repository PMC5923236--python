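"""Delimited-text readers/writers for window maps, registered sets and labels.

Window maps are CSV: header row of frame times in seconds, first column the
window id, empty cells marking missing values.  Registered sets are CSV
matrices with a JSON sidecar carrying provenance, kind, onset column and
parameters, so every result file is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from edgeclust.registration import RegisteredSeriesSet, WindowTimeSeriesMap

__all__ = [
    "write_map",
    "read_map",
    "write_registered",
    "read_registered",
    "write_labels",
    "read_labels",
]


def write_map(tsmap: WindowTimeSeriesMap, path: str | Path) -> None:
    path = Path(path)
    times = np.arange(tsmap.n_frames) * tsmap.frame_interval_s
    values = tsmap.values.astype(object)
    values[tsmap.missing_mask] = ""
    with path.open("w") as fh:
        fh.write("window," + ",".join(f"{t:g}" for t in times) + "\n")
        for wid, row in zip(tsmap.window_ids, values):
            fh.write(str(wid) + "," + ",".join("" if v == "" else f"{v:.10g}" for v in row) + "\n")


def read_map(path: str | Path, kind: str = "velocity") -> WindowTimeSeriesMap:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header = lines[0].split(",")
    n_cols = len(header)
    times = np.array([float(t) for t in header[1:]])
    ids, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise ValueError(f"ragged row at line {ln}: expected {n_cols} cells, got {len(cells)}")
        ids.append(cells[0])
        rows.append([np.nan if c.strip() in ("", "NA", "NaN", "nan") else float(c) for c in cells[1:]])
    values = np.asarray(rows, dtype=float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 5.0
    return WindowTimeSeriesMap(values=values, frame_interval_s=dt, kind=kind, window_ids=ids)


def write_registered(rset: RegisteredSeriesSet, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(rset.matrix).to_csv(path, index=False, header=False)
    sidecar = {
        "kind": rset.kind,
        "onset_column": rset.onset_column,
        "frame_interval_s": rset.frame_interval_s,
        "provenance": [[m, int(w), int(f)] for m, w, f in rset.provenance],
        "params": params or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_registered(path: str | Path) -> RegisteredSeriesSet:
    path = Path(path)
    matrix = pd.read_csv(path, header=None).to_numpy(dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return RegisteredSeriesSet(
            matrix=matrix,
            onset_column=meta.get("onset_column", 5),
            provenance=[tuple(p) for p in meta.get("provenance", [])] or None or [],
            kind=meta.get("kind", "velocity"),
            frame_interval_s=meta.get("frame_interval_s", 5.0),
        )
    return RegisteredSeriesSet(matrix=matrix)


def write_labels(labels: np.ndarray, path: str | Path, sample_ids: list | None = None) -> None:
    labels = np.asarray(labels)
    ids = sample_ids if sample_ids is not None else list(range(len(labels)))
    pd.DataFrame({"sample_id": ids, "cluster": labels}).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["cluster"].to_numpy()
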