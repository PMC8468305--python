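"""Stride-scale kinematics from planar position time series.

Operators: instantaneous speed from consecutive displacements, forward
acceleration as its time derivative, signed path curvature from the
circumradius of three consecutive points (κ = 4·area / (a·b·c), sign from
the turn direction; counter-clockwise positive), yaw rate ω = s·κ,
centripetal acceleration a_c = s²·|κ|, total acceleration as the vector sum
of the orthogonal tangential and normal components, and stride jerk — the
per-stride difference of centripetal acceleration divided by the stride
period.

Two stride-frequency constants coexist deliberately: curvature is estimated
on series resampled at the mean gallop frequency 3.34 Hz, while the jerk of
Eq-style per-stride differencing assumes a stride frequency of 3.54 Hz; both
are configuration keys and each default follows its use.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

#: stride frequency assumed by the per-stride jerk, Hz
DEFAULT_JERK_STRIDE_HZ = 3.54
#: stride frequency used to resample position data for curvature, Hz
DEFAULT_RESAMPLE_HZ = 3.34


class StrideConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stride_frequency: float = Field(default=DEFAULT_JERK_STRIDE_HZ, gt=0.0)


def instantaneous_speed(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Speed from per-interval Euclidean displacement over the time step.

    Interval speeds are assigned to interval midpoints and interpolated back
    onto the sample grid (edge values extended). Non-negative by
    construction.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    v_mid = np.hypot(np.diff(x), np.diff(y)) / dt
    t_mid = t[:-1] + dt / 2.0
    return np.interp(t, t_mid, v_mid)


def forward_acceleration(t: np.ndarray, speed: np.ndarray) -> np.ndarray:
    """Finite-difference time derivative of speed (central interior,
    one-sided at the ends)."""
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    return np.gradient(speed, t)


def circumradius_curvature(p1, p2, p3) -> float:
    """Signed curvature of the circle through three points, 1/m.

    |κ| = 4·(triangle area) / (product of side lengths); the sign is that of
    the cross product (p2−p1)×(p3−p2), so a counter-clockwise turn is
    positive. Collinear points give exactly 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = p2 - p1
    b = p3 - p2
    c = p3 - p1
    la, lb, lc = np.hypot(*a), np.hypot(*b), np.hypot(*c)
    if la == 0 or lb == 0 or lc == 0:
        raise ValueError("coincident points have no circumcircle")
    cross = a[0] * b[1] - a[1] * b[0]
    return float(2.0 * cross / (la * lb * lc))


def curvature_series(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed circumradius curvature at every sample from consecutive triples.

    κ[i] is estimated from points (i−1, i, i+1); the first and last samples
    take their neighbour's value so the output aligns with the input grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for curvature")
    ax = x[1:-1] - x[:-2]
    ay = y[1:-1] - y[:-2]
    bx = x[2:] - x[1:-1]
    by = y[2:] - y[1:-1]
    cx = x[2:] - x[:-2]
    cy = y[2:] - y[:-2]
    la = np.hypot(ax, ay)
    lb = np.hypot(bx, by)
    lc = np.hypot(cx, cy)
    prod = la * lb * lc
    if np.any(prod == 0):
        raise ValueError("coincident points in the series")
    cross = ax * by - ay * bx
    kappa = np.empty(n)
    kappa[1:-1] = 2.0 * cross / prod
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    return kappa


def radius_from_curvature(kappa):
    """Turning radius 1/|κ| in metres; κ = 0 signals a straight (inf)."""
    arr = np.asarray(kappa, dtype=float)
    with np.errstate(divide="ignore"):
        r = 1.0 / np.abs(arr)
    if np.ndim(kappa) == 0:
        return float(r)
    return r


def yaw_rate(speed, kappa):
    """Signed heading rate ω = s·κ, rad/s (counter-clockwise positive)."""
    return np.multiply(speed, kappa)


def centrifugal_acceleration(speed, kappa):
    """Centripetal acceleration magnitude a_c = s²·|κ|, m/s²."""
    return np.multiply(np.square(speed), np.abs(kappa))


def total_acceleration(a_fwd, a_c):
    """Vector sum of the orthogonal tangential and normal components."""
    return np.hypot(a_fwd, a_c)


def stride_jerk(
    a_c: np.ndarray,
    stride_frequency: float = DEFAULT_JERK_STRIDE_HZ,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Per-stride jerk: (a_c of next stride − a_c) / stride period, m/s³.

    One element shorter than the input, aligned to the leading sample. If
    timestamps are given, they must form a uniform grid.
    """
    a_c = np.asarray(a_c, dtype=float)
    if stride_frequency <= 0:
        raise ValueError("stride_frequency must be positive")
    if t is not None:
        # tolerance covers timestamps round-tripped at 6 decimal places
        dt = np.diff(np.asarray(t, dtype=float))
        if len(dt) and not np.allclose(dt, np.mean(dt), rtol=1e-4, atol=2e-6):
            raise ValueError("series is not uniformly sampled")
    return np.diff(a_c) * stride_frequency


#: column layout of an exported kinematic series
SERIES_COLUMNS = [
    "t_s",
    "dist_m",
    "speed_mps",
    "acc_fwd_mps2",
    "curvature_1pm",
    "yaw_radps",
    "acc_cent_mps2",
    "acc_total_mps2",
    "jerk_mps3",
]


def compute_kinematics(
    df: pd.DataFrame,
    jerk_stride_frequency: float = DEFAULT_JERK_STRIDE_HZ,
) -> pd.DataFrame:
    """All kinematic series for one subject's (t_s, x_m, y_m) stream.

    The input is expected on a uniform (stride-resampled) grid. The distance
    axis is the cumulative path distance of the trajectory itself. Jerk is
    aligned to the leading sample; its last element is NaN.
    """
    t = df["t_s"].to_numpy(dtype=float)
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    chord = np.hypot(np.diff(x), np.diff(y))
    dist = np.concatenate([[0.0], np.cumsum(chord)])
    speed = instantaneous_speed(t, x, y)
    acc_fwd = forward_acceleration(t, speed)
    kappa = curvature_series(x, y)
    omega = yaw_rate(speed, kappa)
    a_c = centrifugal_acceleration(speed, kappa)
    a_tot = total_acceleration(acc_fwd, a_c)
    jerk = np.full(len(t), np.nan)
    jerk[:-1] = stride_jerk(a_c, jerk_stride_frequency, t=t)
    return pd.DataFrame(
        {
            "t_s": t,
            "dist_m": dist,
            "speed_mps": speed,
            "acc_fwd_mps2": acc_fwd,
            "curvature_1pm": kappa,
            "yaw_radps": omega,
            "acc_cent_mps2": a_c,
            "acc_total_mps2": a_tot,
            "jerk_mps3": jerk,
        }
    )
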