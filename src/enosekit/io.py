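"""Plain-text persistence for traces, feature matrices and reports.

Traces travel in a long-format CSV (one row per sample, sensor and
time point) with a sidecar manifest CSV holding per-sample metadata
(acid value) plus provenance and the sensor order.  Feature matrices
travel in a wide CSV, one row per sample.  Reports are JSON.  All
files are UTF-8, comma-separated, decimal point ``.``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import FeatureMatrix
from .samples import SampleRecord, SampleSet, SensorTrace

__all__ = [
    "write_traces",
    "read_traces",
    "write_feature_matrix",
    "read_feature_matrix",
    "manifest_path_for",
    "dump_json",
]

TRACE_COLUMNS = ["sample_id", "grade", "sensor_id", "time_s", "response"]
MANIFEST_COLUMNS = ["sample_id", "grade", "acid_value"]


def manifest_path_for(traces_path: str | Path) -> Path:
    traces_path = Path(traces_path)
    return traces_path.with_name(traces_path.stem + ".manifest.csv")


def write_traces(sample_set: SampleSet, destination: str | Path) -> Path:
    """Write the long-format trace CSV plus its sidecar manifest."""
    destination = Path(destination)
    frames = []
    for rec in sample_set:
        for tr in rec.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": rec.sample_id,
                        "grade": rec.grade,
                        "sensor_id": tr.sensor_id,
                        "time_s": tr.times,
                        "response": tr.values,
                    }
                )
            )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=TRACE_COLUMNS)
    table.to_csv(destination, index=False)

    manifest = pd.DataFrame(
        {
            "sample_id": [rec.sample_id for rec in sample_set],
            "grade": [rec.grade for rec in sample_set],
            "acid_value": [rec.acid_value for rec in sample_set],
        },
        columns=MANIFEST_COLUMNS,
    )
    mpath = manifest_path_for(destination)
    with open(mpath, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance: {sample_set.provenance}\n")
        fh.write(f"# sensors: {','.join(sample_set.sensor_ids)}\n")
        manifest.to_csv(fh, index=False)
    return destination


def _natural_key(label: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", label))


def _read_manifest(mpath: Path) -> tuple[str, list[str], dict[str, float]]:
    provenance, sensor_order = "", []
    with open(mpath, encoding="utf-8") as fh:
        head = fh.readline()
        while head.startswith("#"):
            body = head[1:].strip()
            if body.startswith("provenance:"):
                provenance = body.split(":", 1)[1].strip()
            elif body.startswith("sensors:"):
                sensor_order = [
                    s for s in body.split(":", 1)[1].strip().split(",") if s
                ]
            head = fh.readline()
    table = pd.read_csv(mpath, comment="#")
    acid: dict[str, float] = {}
    if "acid_value" in table.columns:
        for sid, value in zip(table["sample_id"].astype(str), table["acid_value"]):
            if pd.notna(value):
                acid[sid] = float(value)
    return provenance, sensor_order, acid


def read_traces(source: str | Path) -> SampleSet:
    """Load a trace CSV (order-insensitive) and validate its structure."""
    source = Path(source)
    table = pd.read_csv(source)
    missing = set(TRACE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{source.name}: missing columns {sorted(missing)}")

    provenance, sensor_order, acid = "", [], {}
    mpath = manifest_path_for(source)
    if mpath.exists():
        provenance, sensor_order, acid = _read_manifest(mpath)

    if table.empty:
        return SampleSet([], provenance=provenance)

    if not sensor_order:
        sensor_order = sorted(table["sensor_id"].astype(str).unique(), key=_natural_key)

    records = []
    for sample_id, sample_rows in table.groupby("sample_id", sort=True):
        sample_id = str(sample_id)
        grades = sample_rows["grade"].unique()
        if len(grades) != 1:
            raise SchemaError(f"sample {sample_id!r}: inconsistent grade labels")
        traces = []
        lengths = set()
        for sensor_id, rows in sample_rows.groupby("sensor_id"):
            rows = rows.sort_values("time_s")
            times = rows["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(times) == 0):
                raise SchemaError(f"sample {sample_id!r}: duplicate time_s values")
            traces.append(
                SensorTrace(str(sensor_id), times, rows["response"].to_numpy(dtype=float))
            )
            lengths.add(times.size)
        if len(lengths) != 1:
            raise SchemaError(f"sample {sample_id!r}: ragged trace lengths {sorted(lengths)}")
        order = {sid: i for i, sid in enumerate(sensor_order)}
        traces.sort(key=lambda tr: order.get(tr.sensor_id, len(order)))
        records.append(
            SampleRecord(
                sample_id,
                int(grades[0]),
                tuple(traces),
                acid_value=acid.get(sample_id),
            )
        )
    return SampleSet(records, provenance=provenance)


def write_feature_matrix(fm: FeatureMatrix, destination: str | Path) -> Path:
    destination = Path(destination)
    fm.to_frame().to_csv(destination, index=False)
    return destination


def read_feature_matrix(source: str | Path) -> FeatureMatrix:
    source = Path(source)
    with open(source, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise SchemaError(f"{source.name}: duplicate column names in header")
    return FeatureMatrix.from_frame(pd.read_csv(source))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def dump_json(payload: Any, path: str | Path) -> Path:
    """Deterministic JSON writer (sorted keys, native floats)."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path
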