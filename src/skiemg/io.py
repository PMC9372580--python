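"""Read/write session containers and tidy metric tables.

A session container is a directory holding one ``meta.json`` (identity,
run markers, MVC references, channel registry) and one numeric CSV per
channel (``time_s,value``; RFC-4180, "." decimal separator, UTF-8).
Timestamps are seconds from session start as float64; sampling rates are
stored explicitly in the metadata, never inferred from timestamps. The
metrics table is tidy long-format CSV, one metric per row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CHANNEL_SCHEMA,
    Channel,
    RunMarker,
    SessionRecording,
    TurnMetricsRow,
    ValidationError,
)

META_NAME = "meta.json"
TRUTH_NAME = "ground_truth.json"

METRICS_COLUMNS = [
    "session_id",
    "discipline",
    "run_index",
    "run_label",
    "cycle_index",
    "leg",
    "signal",
    "metric",
    "value",
]


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session container; the target directory is created."""
    rec.validate()
    path = Path(path)
    (path / "channels").mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": rec.session_id,
        "discipline": rec.discipline,
        "run_markers": [
            {"run_index": m.run_index, "start_s": m.start_s, "end_s": m.end_s, "complete": m.complete}
            for m in rec.run_markers
        ],
        "mvc_references": rec.mvc_references,
        "channels": {
            name: {"rate_hz": ch.rate_hz, "units": ch.units, "n_samples": int(len(ch.samples))}
            for name, ch in rec.channels.items()
        },
    }
    (path / META_NAME).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    for name, ch in rec.channels.items():
        df = pd.DataFrame({"time_s": ch.times(), "value": ch.samples})
        df.to_csv(path / "channels" / f"{name}.csv", index=False, float_format="%.17g")
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read and validate a session container; round-trips :func:`write_session`."""
    path = Path(path)
    meta_path = path / META_NAME
    if not meta_path.exists():
        raise ValidationError(META_NAME, f"not found under {path}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    channels: dict[str, Channel] = {}
    for name in CHANNEL_SCHEMA:
        if name not in meta.get("channels", {}):
            raise ValidationError(name, "channel missing from metadata")
        info = meta["channels"][name]
        csv_path = path / "channels" / f"{name}.csv"
        if not csv_path.exists():
            raise ValidationError(name, f"channel file {csv_path.name} missing")
        df = pd.read_csv(csv_path, float_precision="round_trip")
        if list(df.columns) != ["time_s", "value"]:
            raise ValidationError(name, f"unexpected columns {list(df.columns)}")
        samples = df["value"].to_numpy(dtype=float)
        if len(samples) != info["n_samples"]:
            raise ValidationError(name, f"{len(samples)} samples on disk, {info['n_samples']} in metadata")
        start = float(df["time_s"].iloc[0]) if len(df) else 0.0
        channels[name] = Channel(float(info["rate_hz"]), samples, units=info.get("units", ""), start_s=start)
    markers = [
        RunMarker(int(m["run_index"]), float(m["start_s"]), float(m["end_s"]), bool(m["complete"]))
        for m in meta["run_markers"]
    ]
    rec = SessionRecording(
        session_id=meta["session_id"],
        discipline=meta["discipline"],
        channels=channels,
        run_markers=markers,
        mvc_references={k: float(v) for k, v in meta.get("mvc_references", {}).items()},
    )
    rec.validate()
    return rec


def write_ground_truth(truth, path: str | Path) -> Path:
    """Write the generator's GroundTruth sidecar next to a session container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=1), encoding="utf-8")
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def rows_to_frame(rows: list[TurnMetricsRow]) -> pd.DataFrame:
    for r in rows:
        r.validate()
    if not rows:
        return pd.DataFrame(columns=METRICS_COLUMNS)
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df[METRICS_COLUMNS]


def write_metrics_table(rows, path: str | Path) -> Path:
    """Write the tidy per-turn metrics table (validates every row)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
        missing = [c for c in METRICS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(missing[0], "column missing from metrics table")
        for rec in df.itertuples(index=False):
            TurnMetricsRow(**{c: getattr(rec, c) for c in METRICS_COLUMNS}).validate()
        df = df[METRICS_COLUMNS]
    else:
        df = rows_to_frame(list(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "session_id": str,
            "discipline": str,
            "run_index": np.int64,
            "run_label": str,
            "cycle_index": np.int64,
            "leg": str,
            "signal": str,
            "metric": str,
            "value": float,
        },
        keep_default_na=False,
        na_values=[],
        float_precision="round_trip",
    )
    if list(df.columns) != METRICS_COLUMNS:
        raise ValidationError("columns", f"unexpected metrics columns {list(df.columns)}")
    return df
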