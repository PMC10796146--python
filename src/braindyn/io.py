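"""Plain-text serialization of records, rasters, and analysis tables.

Monitor series go to CSV with one time column and one column per monitored
scalar (array monitors are flattened with index-suffixed headers); run
metadata is JSON; spike rasters are two-column event CSVs (time_ms,
neuron_id).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SimulationRecord

__all__ = [
    "record_to_csv",
    "spikes_to_csv",
    "write_json",
    "read_json",
    "fixed_points_to_csv",
    "file_sha256",
]


def _json_default(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def record_to_csv(record: SimulationRecord, target: str, path) -> None:
    """Write one monitored series: time column plus per-scalar columns."""
    series = record.series[target]
    times = record.times[target]
    cols = {"time_ms": times}
    if series.ndim == 1:
        cols[target] = series
    else:
        flat = series.reshape(len(series), -1)
        for i in range(flat.shape[1]):
            cols[f"{target}_{i}"] = flat[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def spikes_to_csv(record: SimulationRecord, target: str, path) -> None:
    """Write a boolean spike monitor as a two-column event CSV."""
    raster = record.series[target]
    times = record.times[target]
    steps, neurons = np.nonzero(np.atleast_2d(raster.astype(bool)))
    pd.DataFrame({
        "time_ms": times[steps],
        "neuron_id": neurons,
    }).to_csv(path, index=False, float_format="%.17g")


def fixed_points_to_csv(points, path) -> None:
    """Tabulate fixed points: coordinates, residual q, labels, eigenvalues."""
    rows = []
    for fp in points:
        row = {f"x{i}": v for i, v in enumerate(np.atleast_1d(fp.x))}
        row["q"] = fp.q
        row["label"] = fp.label
        for i, ev in enumerate(np.atleast_1d(fp.eigenvalues)):
            row[f"eig{i}_re"] = np.real(ev)
            row[f"eig{i}_im"] = np.imag(ev)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
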