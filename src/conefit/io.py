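"""Manifest handling, trace CSV round-trips, result serialization.

Traces travel as two-column CSV (time_s, V_mV); a JSON manifest binds series
ids to files, condition labels, stimulant levels and optional step-artifact
annotations.  Results serialize to JSON with a schema version, the seeds used
and a hash of the originating configuration, so runs are diffable and
attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset, condition_from_label
from .preprocess import MpTimeSeries, RawTrace, StepArtifact

__all__ = [
    "SCHEMA_VERSION",
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
    "load_manifest",
    "load_dataset",
    "load_raw_traces",
    "save_dataset",
    "save_results",
    "config_hash",
]

SCHEMA_VERSION = 1


def write_trace_csv(path, times, values) -> None:
    pd.DataFrame({"time_s": times, "V_mV": values}).to_csv(path, index=False)


def read_trace_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("time_s", "V_mV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df["time_s"].to_numpy(float), df["V_mV"].to_numpy(float)


def config_hash(config) -> str:
    """Stable short hash of any JSON-serializable (or dataclass) config."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, entries: list[dict], description: str = "", seed=None) -> None:
    """entries: [{file, series_id, condition_label, stimulant_uM, sigma_i?, annotations?}]"""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "description": description,
        "seed": seed,
        "series": entries,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_manifest(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if "series" not in doc:
        raise ValueError(f"{path}: manifest has no 'series' list")
    ids = [e["series_id"] for e in doc["series"]]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate series ids in manifest")
    return doc


def load_dataset(manifest_path) -> Dataset:
    """Load preprocessed 1 Hz series listed in a manifest."""
    manifest_path = Path(manifest_path)
    doc = load_manifest(manifest_path)
    root = manifest_path.parent
    series, conds = [], []
    for entry in doc["series"]:
        fp = root / entry["file"]
        if not fp.exists():
            raise FileNotFoundError(
                f"series {entry['series_id']!r}: trace file {fp} does not exist"
            )
        times, values = read_trace_csv(fp)
        if len(times) >= 2 and not np.allclose(np.diff(times), 1.0):
            raise ValueError(f"series {entry['series_id']!r}: grid is not uniform 1 s")
        series.append(
            MpTimeSeries(
                series_id=entry["series_id"],
                condition_label=entry["condition_label"],
                values=values,
                sigma_i=entry.get("sigma_i"),
            )
        )
        conds.append(
            condition_from_label(
                entry["condition_label"], S_max=float(entry.get("stimulant_uM", 10.0))
            )
        )
    return Dataset(series=series, conditions=conds, description=doc.get("description", ""))


def save_dataset(dataset: Dataset, out_dir, seed=None) -> Path:
    """Write one CSV per series plus manifest.json; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s, c in dataset:
        fname = f"{s.series_id}.csv"
        write_trace_csv(out_dir / fname, s.times, s.values)
        entries.append(
            {
                "file": fname,
                "series_id": s.series_id,
                "condition_label": s.condition_label,
                "stimulant_uM": c.S_max,
                "sigma_i": s.sigma_i,
            }
        )
    manifest = out_dir / "manifest.json"
    write_manifest(manifest, entries, description=dataset.description, seed=seed)
    return manifest


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_results(result, path, seed=None, config=None) -> None:
    """JSON envelope: schema version, seed, config hash, then the payload."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_raw_traces(manifest_path) -> list[tuple[RawTrace, list[StepArtifact]]]:
    """Raw (pre-decimation) traces plus any step annotations from a manifest."""
    manifest_path = Path(manifest_path)
    doc = load_manifest(manifest_path)
    root = manifest_path.parent
    out = []
    for entry in doc["series"]:
        fp = root / entry["file"]
        if not fp.exists():
            raise FileNotFoundError(
                f"series {entry['series_id']!r}: trace file {fp} does not exist"
            )
        times, values = read_trace_csv(fp)
        raw = RawTrace(times=times, values=values,
                       series_id=entry["series_id"],
                       condition_label=entry["condition_label"])
        anns = [
            StepArtifact(a["onset_index"], a["end_index"], a.get("offset", 0.0))
            for a in entry.get("annotations", [])
        ]
        out.append((raw, anns))
    return out
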