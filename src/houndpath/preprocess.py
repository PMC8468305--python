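"""Tracking-data cleaning chain.

The cleaning applied to each subject's coordinate stream, in order:

1. trim the unreliable start window (box interference),
2. replace outliers — samples whose residual from a centred moving average
   exceeds k (default 3) local standard deviations are swapped for the
   moving-average value,
3. centred moving-average smoothing,
4. linear resampling onto a uniform grid at the mean stride frequency
   (3.34 Hz), so that consecutive samples are about one gallop stride apart.

x and y are screened independently, but a sample flagged in either axis is
replaced in both: a planar fix is either trusted or it is not.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .recording import RaceRecording


class CleaningConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: centred moving-average window, samples (odd); ~0.17 s at 30 Hz,
    #: safely below the ~0.3 s stride period
    ma_window: int = Field(default=5, ge=1)
    #: outlier threshold in multiples of the local residual SD
    outlier_k: float = Field(default=3.0, gt=0.0)
    #: window for the rolling residual SD, samples
    sd_window: int = Field(default=31, ge=3)
    #: seconds removed from the start of every subject's stream
    trim_start: float = Field(default=1.0, ge=0.0)
    #: resampling target, Hz (the mean gallop stride frequency)
    stride_frequency_resample: float = Field(default=3.34, gt=0.0)

    @field_validator("ma_window")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError(f"ma_window must be odd (got {v})")
        return v


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with window shrinkage at the ends.

    Output length equals input length; a window of 1 is the identity.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1 (got {window})")
    if window % 2 == 0:
        raise ValueError(f"window must be odd (got {window})")
    if window > len(values):
        raise ValueError(
            f"window {window} exceeds series length {len(values)}"
        )
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def replace_outliers(
    values: np.ndarray,
    k: float = 3.0,
    window: int = 5,
    sd_window: int = 31,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace samples deviating more than k local SDs from a moving average.

    Residuals are taken against the centred moving average of ``window``
    samples; a sample is flagged when its residual deviates from the local
    residual mean by more than k rolling standard deviations (both over
    ``sd_window`` samples — comparing against the local mean keeps the slow,
    smooth filter bias on curved sections from masquerading as outliers).
    Flagged samples are replaced by the moving-average value; everything
    else passes through untouched. Returns (cleaned, mask).

    Positions where either rolling window is truncated (near the series
    ends) are never flagged: window shrinkage biases the residual and its
    scale estimate there even on perfectly smooth data. Windows whose
    residual SD is degenerate — zero, or below a micrometre, i.e. orders of
    magnitude under any positioning resolution — flag nothing.
    """
    values = np.asarray(values, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be positive (got {k})")
    if len(values) < max(window, sd_window):
        raise ValueError(
            f"series of length {len(values)} shorter than window "
            f"({max(window, sd_window)})"
        )
    ma = moving_average(values, window)
    resid = values - ma
    # full windows only: truncated windows near the ends give unreliable
    # scale estimates, so those positions are never flagged
    roll = pd.Series(resid).rolling(sd_window, center=True, min_periods=sd_window)
    sd = roll.std().to_numpy()
    local_mean = roll.mean().to_numpy()
    with np.errstate(invalid="ignore"):
        mask = np.abs(resid - local_mean) > k * sd
    mask &= np.isfinite(sd) & (sd > 1e-6)
    half = (window - 1) // 2
    if half > 0:
        mask[:half] = False
        mask[len(values) - half:] = False
    out = values.copy()
    out[mask] = ma[mask]
    return out, mask


def trim_start(recording: RaceRecording, trim: float) -> RaceRecording:
    """Drop all samples earlier than ``trim`` seconds from every subject."""
    if trim < 0:
        raise ValueError(f"trim must be non-negative (got {trim})")
    out = recording.copy()
    if trim == 0:
        return out
    out.data = out.data[out.data["t_s"] >= trim].reset_index(drop=True)
    if out.data.empty:
        warnings.warn(
            f"trim of {trim} s removed every sample", stacklevel=2
        )
    return out


def resample_to_frequency(df: pd.DataFrame, target: float) -> pd.DataFrame:
    """Linear interpolation of (t_s, x_m, y_m) onto a uniform grid.

    The grid starts at the first timestamp and covers the original time
    range at ``target`` Hz: 1 + floor(duration · target) samples.
    """
    if target <= 0:
        raise ValueError(f"target frequency must be positive (got {target})")
    if len(df) < 2:
        raise ValueError("need at least 2 samples to resample")
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    n = 1 + int(np.floor((t[-1] - t[0]) * target + 1e-9))
    grid = t[0] + np.arange(n) / target
    out = pd.DataFrame(
        {
            "t_s": grid,
            "x_m": np.interp(grid, t, df["x_m"].to_numpy(dtype=float)),
            "y_m": np.interp(grid, t, df["y_m"].to_numpy(dtype=float)),
        }
    )
    return out


def clean_recording(
    recording: RaceRecording, config: CleaningConfig | None = None
) -> tuple[RaceRecording, pd.DataFrame]:
    """Full cleaning chain: trim → outlier replacement → smoothing → resample.

    Returns the cleaned recording (on the stride-frequency grid) and the
    outlier table with columns ``t_s, subject_id, axis, original, replaced``.
    """
    config = config or CleaningConfig()
    trimmed = trim_start(recording, config.trim_start)
    frames = {}
    outlier_rows = []
    for sid in trimmed.subjects:
        sub = trimmed.subject_frame(sid)
        if len(sub) < max(config.ma_window, config.sd_window):
            warnings.warn(
                f"subject {sid!r} has too few samples after trimming; skipped",
                stacklevel=2,
            )
            continue
        t = sub["t_s"].to_numpy(dtype=float)
        x = sub["x_m"].to_numpy(dtype=float)
        y = sub["y_m"].to_numpy(dtype=float)
        ma_x = moving_average(x, config.ma_window)
        ma_y = moving_average(y, config.ma_window)
        _, mx = replace_outliers(x, config.outlier_k, config.ma_window, config.sd_window)
        _, my = replace_outliers(y, config.outlier_k, config.ma_window, config.sd_window)
        both = mx | my  # a flag in either axis distrusts the planar fix
        for j in np.where(both)[0]:
            for axis, arr, ma in (("x", x, ma_x), ("y", y, ma_y)):
                outlier_rows.append(
                    {
                        "t_s": t[j],
                        "subject_id": sid,
                        "axis": axis,
                        "original": arr[j],
                        "replaced": ma[j],
                    }
                )
        x = np.where(both, ma_x, x)
        y = np.where(both, ma_y, y)
        x = moving_average(x, config.ma_window)
        y = moving_average(y, config.ma_window)
        frames[sid] = resample_to_frequency(
            pd.DataFrame({"t_s": t, "x_m": x, "y_m": y}),
            config.stride_frequency_resample,
        )
    from .recording import from_subject_frames

    meta = dict(recording.metadata)
    meta["cleaning"] = config.model_dump()
    cleaned = from_subject_frames(frames, meta)
    outliers = pd.DataFrame(
        outlier_rows, columns=["t_s", "subject_id", "axis", "original", "replaced"]
    )
    return cleaned, outliers
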