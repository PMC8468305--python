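"""Race-then-cohort aggregation of kinematic quantities.

Cohort statistics are two-stage: each quantity is first averaged within a
race (across that race's subjects and samples, per distance bin), and the
per-race bin means are then averaged across races. The min/max envelope per
bin is kept alongside the mean. An optional 3-SD screen can be re-applied to
the per-race bin values before averaging, mirroring the final outlier pass
of the cleaning procedure; bins with no coverage are reported absent rather
than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import RaceRecording
from .track import TrackPath, perpendicular_distance


@dataclass
class CohortProfile:
    """Distance-binned cohort statistics for one kinematic quantity."""

    quantity: str
    label: str
    table: pd.DataFrame  # columns: bin_centre_m, mean, min, max, n

    def __post_init__(self) -> None:
        required = ["bin_centre_m", "mean", "min", "max", "n"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"profile table missing columns: {missing}")
        bad = (self.table["min"] > self.table["mean"] + 1e-12) | (
            self.table["mean"] > self.table["max"] + 1e-12
        )
        if bad.any():
            raise ValueError("envelope violated: need min <= mean <= max")
        if (self.table["n"] < 1).any():
            raise ValueError("every reported bin needs n >= 1")

    def to_csv(self, file) -> None:
        self.table.to_csv(file, index=False, float_format="%.6f")


def make_bins(race_distance: float, width: float = 5.0) -> np.ndarray:
    """Distance bin edges covering [0, race_distance]."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    n = int(np.ceil(race_distance / width))
    return np.arange(n + 1) * width


def race_profile(
    series: pd.DataFrame | list[pd.DataFrame],
    bin_edges: np.ndarray,
    quantities: list[str] | None = None,
    distance_column: str = "dist_m",
) -> pd.DataFrame:
    """Bin-average each quantity over one race.

    ``series`` is one subject's kinematic frame or a list of them (all
    subjects of the race); the race value in a bin is the mean of every
    sample falling in it.
    """
    if isinstance(series, pd.DataFrame):
        frames = [series]
    else:
        frames = list(series)
    if not frames or all(len(f) == 0 for f in frames):
        raise ValueError("empty series")
    df = pd.concat(frames, ignore_index=True)
    if quantities is None:
        quantities = [
            c for c in df.columns if c not in ("t_s", distance_column, "subject_id")
        ]
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with positive width")
    idx = pd.cut(df[distance_column], edges, include_lowest=True)
    grouped = df.groupby(idx, observed=False)[quantities].mean()
    centres = (edges[:-1] + edges[1:]) / 2.0
    out = grouped.reset_index(drop=True)
    out.insert(0, "bin_centre_m", centres)
    return out


def cohort_average(
    profiles: list[pd.DataFrame],
    quantity: str,
    label: str = "",
    sd_filter_k: float | None = None,
) -> CohortProfile:
    """Two-stage average of per-race profiles, with a min/max envelope.

    All profiles must share the same binning. ``sd_filter_k`` re-applies the
    k-SD outlier rule to the per-race bin values before averaging (values
    further than k cohort SDs from the bin mean are dropped); None disables
    the screen.
    """
    if not profiles:
        raise ValueError("need at least one race profile")
    centres = profiles[0]["bin_centre_m"].to_numpy(dtype=float)
    for p in profiles[1:]:
        c = p["bin_centre_m"].to_numpy(dtype=float)
        if len(c) != len(centres) or not np.allclose(c, centres):
            raise ValueError("race profiles have mismatched bins")
    values = np.stack(
        [p[quantity].to_numpy(dtype=float) for p in profiles], axis=0
    )  # (races, bins)
    if sd_filter_k is not None and values.shape[0] >= 3:
        finite = np.isfinite(values)
        enough = finite.sum(axis=0) >= 3
        masked = np.ma.masked_invalid(values)
        mu = masked.mean(axis=0).filled(np.nan)
        sd = masked.std(axis=0, ddof=1).filled(np.nan)
        with np.errstate(invalid="ignore"):
            drop = np.abs(values - mu) > sd_filter_k * sd
        drop &= enough & np.isfinite(sd) & (sd > 0)
        values = np.where(drop, np.nan, values)
    n = np.sum(np.isfinite(values), axis=0)
    masked = np.ma.masked_invalid(values)
    mean = np.where(n > 0, masked.mean(axis=0).filled(np.nan), np.nan)
    vmin = np.where(n > 0, masked.min(axis=0).filled(np.nan), np.nan)
    vmax = np.where(n > 0, masked.max(axis=0).filled(np.nan), np.nan)
    table = pd.DataFrame(
        {
            "bin_centre_m": centres,
            "mean": mean,
            "min": vmin,
            "max": vmax,
            "n": n,
        }
    )
    table = table[table["n"] >= 1].reset_index(drop=True)
    return CohortProfile(quantity=quantity, label=label, table=table)


def jerk_envelope(
    profiles: list[pd.DataFrame],
    label: str = "",
    sd_filter_k: float | None = None,
    quantity: str = "jerk_mps3",
) -> CohortProfile:
    """Min/mean/max envelope of per-race jerk profiles across the cohort."""
    return cohort_average(profiles, quantity, label=label, sd_filter_k=sd_filter_k)


def rail_proximity_profile(
    recordings: list[RaceRecording],
    rail: TrackPath,
    bin_edges: np.ndarray,
    label: str = "",
    sd_filter_k: float | None = None,
) -> CohortProfile:
    """Cohort profile of perpendicular distance to the inside rail.

    Per race, every greyhound sample's distance to the rail is binned by
    that subject's cumulative path distance and averaged; races are then
    averaged per bin. The lure is excluded.
    """
    race_frames = []
    for rec in recordings:
        per_subject = []
        for sid in rec.greyhounds:
            sub = rec.subject_frame(sid)
            if len(sub) < 2:
                continue
            xy = sub[["x_m", "y_m"]].to_numpy(dtype=float)
            dist = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))]
            )
            d_perp = perpendicular_distance(xy, rail)
            per_subject.append(
                pd.DataFrame({"dist_m": dist, "rail_distance_m": d_perp})
            )
        if per_subject:
            race_frames.append(
                race_profile(per_subject, bin_edges, ["rail_distance_m"])
            )
    if not race_frames:
        raise ValueError("no usable recordings")
    return cohort_average(
        race_frames, "rail_distance_m", label=label, sd_filter_k=sd_filter_k
    )
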