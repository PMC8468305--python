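"""Readers and writers for the tracking CSV schema and JSON configs.

Tracking CSV: one row per sample, mandatory header ``t_s, subject_id, x_m,
y_m, quality`` (quality optional on input, defaulting to 1). Times are
serialized with 6 decimals and coordinates with 4 (0.1 mm, below every noise
scale), so write∘read∘write is byte-stable. Rows failing validation are
rejected with row-numbered diagnostics — reported in the recording metadata
and as a warning, never silently dropped.

Configs are JSON with strict schemas: unknown keys are errors, which guards
against silently ignored typos.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CleaningConfig
from .recording import COLUMNS, RaceRecording
from .simulate import SimulationConfig
from .track import TrackGeometry

_TRACK_JSON_KEYS = {
    "straight_length_m": "straight_length",
    "bend_radius_ref_m": "bend_radius_ref",
    "rail_offset_ref_m": "rail_offset_ref",
    "start_positions_m": "start_positions",
    "finish_arclength_m": "finish_arclength",
    "cambers_pct": "camber_metadata",
}


def read_tracking_csv(path) -> RaceRecording:
    """Read and validate a tracking CSV into a :class:`RaceRecording`."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["t_s", "subject_id", "x_m", "y_m"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "quality" not in raw.columns:
        raw["quality"] = "1"

    t = pd.to_numeric(raw["t_s"], errors="coerce")
    x = pd.to_numeric(raw["x_m"], errors="coerce")
    y = pd.to_numeric(raw["y_m"], errors="coerce")
    q = pd.to_numeric(raw["quality"], errors="coerce").fillna(1)
    subject = raw["subject_id"].astype(str)

    bad = t.isna() | x.isna() | y.isna() | (t < 0) | (subject.str.len() == 0)
    rejected = []
    for i in np.where(bad.to_numpy())[0]:
        line_no = int(i) + 2  # 1-based, after the header line
        reasons = []
        if pd.isna(t.iloc[i]):
            reasons.append("non-numeric t_s")
        elif t.iloc[i] < 0:
            reasons.append("negative t_s")
        if pd.isna(x.iloc[i]):
            reasons.append("non-numeric x_m")
        if pd.isna(y.iloc[i]):
            reasons.append("non-numeric y_m")
        if len(subject.iloc[i]) == 0:
            reasons.append("empty subject_id")
        rejected.append({"line": line_no, "reason": ", ".join(reasons)})
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} row(s): "
            + "; ".join(f"line {r['line']} ({r['reason']})" for r in rejected[:10]),
            stacklevel=2,
        )
    keep = ~bad
    data = pd.DataFrame(
        {
            "t_s": t[keep].to_numpy(dtype=float),
            "subject_id": subject[keep].to_numpy(),
            "x_m": x[keep].to_numpy(dtype=float),
            "y_m": y[keep].to_numpy(dtype=float),
            "quality": q[keep].to_numpy(dtype=int),
        }
    )
    data = data.sort_values(["subject_id", "t_s"], kind="mergesort").reset_index(
        drop=True
    )
    rec = RaceRecording(data, {"source": str(path), "rejected_rows": rejected})
    for sid, grp in rec.data.groupby("subject_id"):
        dt = np.diff(grp["t_s"].to_numpy())
        if np.any(dt <= 0):
            raise ValueError(
                f"{path}: time not strictly increasing for subject {sid!r}"
            )
    return rec


def write_tracking_csv(recording: RaceRecording, path) -> None:
    """Write a recording in deterministic order (subject, then time)."""
    path = Path(path)
    df = recording.data.sort_values(
        ["subject_id", "t_s"], kind="mergesort"
    ).reset_index(drop=True)
    out = pd.DataFrame(
        {
            "t_s": df["t_s"].map(lambda v: f"{v:.6f}"),
            "subject_id": df["subject_id"].astype(str),
            "x_m": df["x_m"].map(lambda v: f"{v:.4f}"),
            "y_m": df["y_m"].map(lambda v: f"{v:.4f}"),
            "quality": df["quality"].astype(int).astype(str),
        },
        columns=COLUMNS,
    )
    with open(path, "w", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(",".join(row) + "\n")


def write_series_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, float_format="%.6f")


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outliers_csv(outliers: pd.DataFrame, path) -> None:
    outliers.to_csv(path, index=False, float_format="%.6f")


def load_track_config(path) -> TrackGeometry:
    """Track geometry from its JSON schema (strict keys)."""
    with open(path) as fh:
        payload = json.load(fh)
    return track_config_from_dict(payload)


def track_config_from_dict(payload: dict) -> TrackGeometry:
    unknown = set(payload) - set(_TRACK_JSON_KEYS)
    if unknown:
        raise ValueError(f"unknown track config keys: {sorted(unknown)}")
    kwargs = {_TRACK_JSON_KEYS[k]: v for k, v in payload.items()}
    return TrackGeometry(**kwargs)


def dump_track_config(track: TrackGeometry, path) -> None:
    inverse = {v: k for k, v in _TRACK_JSON_KEYS.items()}
    payload = {inverse[k]: v for k, v in track.model_dump().items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_simulation_config(payload: dict) -> SimulationConfig:
    return SimulationConfig(**payload)


def load_cleaning_config(payload: dict) -> CleaningConfig:
    return CleaningConfig(**payload)
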