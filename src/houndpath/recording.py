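"""Per-race container for subject position time series.

A :class:`RaceRecording` holds one race worth of samples for every subject
(the greyhounds plus, optionally, the mechanical lure, whose subject id is
the literal string ``"lure"``). The tabular layout mirrors the tracking CSV
schema: ``t_s, subject_id, x_m, y_m, quality``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["t_s", "subject_id", "x_m", "y_m", "quality"]
LURE_ID = "lure"


@dataclass
class RaceRecording:
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"recording is missing columns: {missing}")
        self.data = self.data.loc[:, COLUMNS].reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique().tolist())

    @property
    def greyhounds(self) -> list[str]:
        return [s for s in self.subjects if s != LURE_ID]

    def subject_frame(self, subject_id: str) -> pd.DataFrame:
        sub = self.data[self.data["subject_id"] == subject_id]
        return sub.sort_values("t_s").reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        """Check the per-subject time monotonicity invariant."""
        for sid, grp in self.data.groupby("subject_id"):
            t = grp["t_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"time not strictly increasing for subject {sid!r}")
        if self.data[["x_m", "y_m"]].isna().any().any():
            raise ValueError("recording contains missing coordinates")

    def median_sample_rate(self, subject_id: str | None = None) -> float:
        sid = subject_id or (self.greyhounds or self.subjects)[0]
        t = self.subject_frame(sid)["t_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("not enough samples to estimate a rate")
        return float(1.0 / np.median(np.diff(t)))

    def copy(self) -> "RaceRecording":
        return RaceRecording(self.data.copy(), dict(self.metadata))


def from_subject_frames(
    frames: dict[str, pd.DataFrame], metadata: dict | None = None
) -> RaceRecording:
    """Assemble a recording from per-subject frames with t_s, x_m, y_m."""
    parts = []
    for sid, df in frames.items():
        part = df.copy()
        part["subject_id"] = sid
        if "quality" not in part.columns:
            part["quality"] = 1
        parts.append(part[COLUMNS])
    data = pd.concat(parts, ignore_index=True)
    data = data.sort_values(["subject_id", "t_s"], kind="mergesort").reset_index(
        drop=True
    )
    return RaceRecording(data, metadata or {})
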