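"""Parametric two-turn oval track model.

The horizontal alignment of a typical two-turn greyhound track is modelled
as a *stadium* curve: two parallel straights joined tangentially by two
semicircular bends. The inside (lure) rail is the stadium at bend radius
``bend_radius_ref - rail_offset_ref``; the published bend radius is measured
on the path ``rail_offset_ref`` (1 m) out from the rail, so with the common
"52 m bend measured 1 m out" the rail itself turns at 51 m.

Coordinate frame: origin at the track centroid, x toward the home straight,
races run counter-clockwise, and counter-clockwise turning carries positive
curvature (right-hand convention). The arc-length datum for every derived
path is the finish line; ``finish_arclength`` locates the finish along the
internal parameterization (measured from the start of the home straight).

Camber percentages are carried as metadata only: the paths produced here are
purely planar and the bends meet the straights without built-in easements,
which is exactly the "sharp" geometry the theoretical track-path jerk is
evaluated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import shapely
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely.geometry import LineString


class TrackGeometry(BaseModel):
    """Dimensions of a two-turn (stadium) track.

    Parameters
    ----------
    straight_length:
        Length of each straight, metres. May be zero (a circular track).
    bend_radius_ref:
        Radius of the semicircular bend measured ``rail_offset_ref`` metres
        out from the inside rail, metres.
    rail_offset_ref:
        The reference offset at which ``bend_radius_ref`` is quoted, metres.
    start_positions:
        Map of race-distance label ("525", ...) to the arc-length position
        of the starting boxes on the reference path, metres from the finish
        datum (measured in the race direction, i.e. boxes sit at
        ``(loop - distance) mod loop``).
    finish_arclength:
        Position of the finish line along the internal parameterization
        (arc length from the start of the home straight), metres.
    camber_metadata:
        Bend/straight camber percentages. Stored only; never used in any
        computation here.
    """

    model_config = ConfigDict(extra="forbid")

    straight_length: float = Field(ge=0.0)
    bend_radius_ref: float = Field(gt=0.0)
    rail_offset_ref: float = Field(gt=0.0)
    start_positions: dict[str, float] = Field(default_factory=dict)
    finish_arclength: float = Field(default=0.0, ge=0.0)
    camber_metadata: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _radius_exceeds_offset(self) -> "TrackGeometry":
        if self.bend_radius_ref <= self.rail_offset_ref:
            raise ValueError(
                "bend_radius_ref must exceed rail_offset_ref "
                f"(got bend_radius_ref={self.bend_radius_ref}, "
                f"rail_offset_ref={self.rail_offset_ref})"
            )
        return self

    @property
    def rail_radius(self) -> float:
        """Bend radius of the inside rail itself, metres."""
        return self.bend_radius_ref - self.rail_offset_ref

    @property
    def reference_loop_length(self) -> float:
        """Closed-loop length of the path at the reference offset."""
        return 2.0 * self.straight_length + 2.0 * math.pi * self.bend_radius_ref

    def loop_length(self, offset: float) -> float:
        """Closed-loop length of the parallel path `offset` m off the rail."""
        return 2.0 * self.straight_length + 2.0 * math.pi * (self.rail_radius + offset)


def build_track(
    straight_length: float,
    bend_radius_ref: float,
    rail_offset_ref: float,
    start_positions: dict[str, float] | None = None,
    finish_arclength: float = 0.0,
    camber_metadata: dict[str, float] | None = None,
) -> TrackGeometry:
    """Validate dimensions and assemble a :class:`TrackGeometry`."""
    return TrackGeometry(
        straight_length=straight_length,
        bend_radius_ref=bend_radius_ref,
        rail_offset_ref=rail_offset_ref,
        start_positions=start_positions or {},
        finish_arclength=finish_arclength,
        camber_metadata=camber_metadata or {},
    )


def default_track() -> TrackGeometry:
    """The study track: 40 m straights, 52 m bends measured 1 m out.

    Start positions for the 525/600/725 m race distances are placed so that
    each race ends at the finish datum (30 m into the home straight) after
    covering its nominal distance along the reference path.
    """
    straight, bend_ref, off_ref, finish = 40.0, 52.0, 1.0, 30.0
    loop = 2 * straight + 2 * math.pi * bend_ref
    starts = {
        label: (-float(label)) % loop for label in ("525", "600", "725")
    }
    return TrackGeometry(
        straight_length=straight,
        bend_radius_ref=bend_ref,
        rail_offset_ref=off_ref,
        start_positions=starts,
        finish_arclength=finish,
        camber_metadata={"bend_pct": 8.0, "straight_pct": 4.0},
    )


@dataclass
class TrackPath:
    """A closed planar path around the track.

    ``vertices`` is an (N, 2) polyline whose first and last vertices
    coincide; ``arclengths`` is the cumulative arc length from the finish
    datum (strictly increasing, last entry = ``loop_length``);
    ``curvature`` holds the signed analytic curvature at each vertex
    (counter-clockwise positive).
    """

    vertices: np.ndarray
    arclengths: np.ndarray
    curvature: np.ndarray
    loop_length: float
    offset: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.arclengths = np.asarray(self.arclengths, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        if len(self.vertices) < 2:
            raise ValueError("a TrackPath needs at least two vertices")
        if np.any(np.diff(self.arclengths) <= 0):
            raise ValueError("arclengths must be strictly increasing")

    @property
    def is_closed(self) -> bool:
        return bool(np.allclose(self.vertices[0], self.vertices[-1], atol=1e-6))

    def polyline_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def point_at(self, s: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the polyline at arc length ``s`` (wraps)."""
        s = np.mod(np.asarray(s, dtype=float), self.loop_length)
        x = np.interp(s, self.arclengths, self.vertices[:, 0])
        y = np.interp(s, self.arclengths, self.vertices[:, 1])
        return np.stack([x, y], axis=-1)

    def curvature_at(self, s: np.ndarray | float) -> np.ndarray | float:
        s = np.mod(np.asarray(s, dtype=float), self.loop_length)
        return np.interp(s, self.arclengths, self.curvature)

    def rolled(self, ds: float) -> "TrackPath":
        """The same loop with the arc-length datum shifted by ``ds``."""
        s = np.mod(self.arclengths[:-1] - ds, self.loop_length)
        order = np.argsort(s)
        verts = self.vertices[:-1][order]
        kappa = self.curvature[:-1][order]
        s = s[order]
        # re-close
        verts = np.vstack([verts, verts[:1]])
        kappa = np.append(kappa, kappa[0])
        s = np.append(s, s[0] + self.loop_length)
        if s[0] > 0:
            s = s - s[0]
        return TrackPath(verts, s, kappa, self.loop_length, self.offset, dict(self.meta))


def _oval_xy_kappa(
    L: float, R: float, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Point and signed curvature of the stadium of straight L, bend radius R.

    Internal parameterization: s = 0 at the start of the home (bottom)
    straight ``(-L/2, -R)`` heading +x; counter-clockwise.
    """
    loop = 2 * L + 2 * math.pi * R
    s = np.mod(np.asarray(s, dtype=float), loop)
    x = np.empty_like(s)
    y = np.empty_like(s)
    kappa = np.zeros_like(s)

    b1, b2, b3 = L, L + math.pi * R, 2 * L + math.pi * R
    m0 = s < b1
    m1 = (s >= b1) & (s < b2)
    m2 = (s >= b2) & (s < b3)
    m3 = s >= b3

    x[m0] = -L / 2 + s[m0]
    y[m0] = -R
    phi = (s[m1] - b1) / R - math.pi / 2  # -pi/2 .. pi/2
    x[m1] = L / 2 + R * np.cos(phi)
    y[m1] = R * np.sin(phi)
    kappa[m1] = 1.0 / R
    x[m2] = L / 2 - (s[m2] - b2)
    y[m2] = R
    phi = (s[m3] - b3) / R + math.pi / 2  # pi/2 .. 3pi/2
    x[m3] = -L / 2 + R * np.cos(phi)
    y[m3] = R * np.sin(phi)
    kappa[m3] = 1.0 / R
    return np.stack([x, y], axis=-1), kappa


def _map_ref_arclength(track: TrackGeometry, s_ref: float, R: float) -> float:
    """Map an arc position on the reference path onto the parallel path of
    bend radius ``R`` (straights map identically, bends by angle)."""
    L = track.straight_length
    R_ref = track.bend_radius_ref
    loop_ref = track.reference_loop_length
    s_ref = float(s_ref) % loop_ref
    b1, b2, b3 = L, L + math.pi * R_ref, 2 * L + math.pi * R_ref
    if s_ref < b1:
        return s_ref
    if s_ref < b2:
        return L + (s_ref - b1) / R_ref * R
    if s_ref < b3:
        return L + math.pi * R + (s_ref - b2)
    return 2 * L + math.pi * R + (s_ref - b3) / R_ref * R


def offset_path(
    track: TrackGeometry, offset: float, vertex_spacing: float = 0.05
) -> TrackPath:
    """Closed polyline at perpendicular ``offset`` from the inside rail.

    The exact analytic curvature profile is attached: zero on the straights,
    ``1/(rail_radius + offset)`` on the bends (positive, counter-clockwise).
    Vertex 0 sits at the finish datum.
    """
    if offset < 0:
        raise ValueError(f"offset must be non-negative (got {offset})")
    R = track.rail_radius + offset
    if R <= 0:
        raise ValueError(
            f"offset {offset} makes the bend path radius non-positive ({R})"
        )
    if vertex_spacing <= 0:
        raise ValueError("vertex_spacing must be positive")
    loop = track.loop_length(offset)
    n = max(int(math.ceil(loop / vertex_spacing)), 8)
    s_local = np.linspace(0.0, loop, n + 1)
    # shift so vertex 0 is the finish datum
    s0 = _map_ref_arclength(track, track.finish_arclength, R)
    pts, kappa = _oval_xy_kappa(track.straight_length, R, s_local + s0)
    pts[-1] = pts[0]
    kappa[-1] = kappa[0]
    return TrackPath(
        vertices=pts,
        arclengths=s_local,
        curvature=kappa,
        loop_length=loop,
        offset=offset,
        meta={"kind": "offset", "bend_radius": R},
    )


def rail_path(track: TrackGeometry, vertex_spacing: float = 0.05) -> TrackPath:
    """The inside (lure) rail itself, i.e. the path at zero offset."""
    return offset_path(track, 0.0, vertex_spacing)


def perpendicular_distance(
    points: np.ndarray, rail: TrackPath
) -> np.ndarray | float:
    """Minimum Euclidean distance from point(s) to the rail polyline, metres.

    Accepts a single (2,) point or an (N, 2) array; returns a float or an
    (N,) array accordingly.
    """
    if rail.vertices is None or len(rail.vertices) < 2:
        raise ValueError("rail polyline is empty or degenerate")
    line = LineString(rail.vertices)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    d = shapely.distance(geoms, line)
    if np.asarray(points).ndim == 1:
        return float(d[0])
    return np.asarray(d, dtype=float)


def stadium_rail_distance(track: TrackGeometry, points: np.ndarray) -> np.ndarray:
    """Closed-form distance to the rail (the stadium boundary).

    The rail is the locus of points at ``rail_radius`` from the segment
    joining the two bend centres, so the distance from any point is
    ``| d(point, segment) - rail_radius |``. Used as the analytic fast path
    and as an independent oracle for :func:`perpendicular_distance`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hx = track.straight_length / 2.0
    qx = np.maximum(np.abs(pts[:, 0]) - hx, 0.0)
    d_seg = np.hypot(qx, pts[:, 1])
    return np.abs(d_seg - track.rail_radius)


def classify_sections(
    track: TrackGeometry, points: np.ndarray, core_margin: float = 0.0
) -> np.ndarray:
    """Label points 'straight', 'bend' or 'transition' by horizontal position.

    ``core_margin`` (metres of arc) trims both sides of each junction so the
    remaining labels are unambiguous cores even for paths with easements.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hx = track.straight_length / 2.0
    labels = np.full(len(pts), "transition", dtype=object)
    on_straight = np.abs(pts[:, 0]) <= hx - core_margin
    labels[on_straight] = "straight"
    beyond = np.abs(pts[:, 0]) > hx
    if np.any(beyond):
        bx = np.sign(pts[beyond, 0]) * hx
        rel = pts[beyond] - np.stack([bx, np.zeros(beyond.sum())], axis=-1)
        r = np.hypot(rel[:, 0], rel[:, 1])
        # angle from the bend centre, measured from the outward x-direction;
        # the junctions sit at +-pi/2
        alpha = np.arctan2(rel[:, 1], np.abs(rel[:, 0]))
        arc_past_junction = (math.pi / 2.0 - np.abs(alpha)) * r
        core = arc_past_junction > core_margin
        idx = np.where(beyond)[0][core]
        labels[idx] = "bend"
    return labels


def theoretical_track_jerk(
    path: TrackPath,
    speed_at: Callable[[np.ndarray], np.ndarray],
    stride_frequency: float,
    *,
    curvature_method: str = "analytic",
    start_distance: float = 0.0,
    total_distance: float | None = None,
    start_arclength: float = 0.0,
    distance_at_time: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Stride-sampled centripetal jerk of following ``path`` exactly.

    A point is marched along the path one stride at a time (stride length =
    instantaneous speed / ``stride_frequency``); at each stride sample the
    centripetal acceleration s²κ is evaluated, and the jerk is the per-stride
    difference divided by the stride period.

    ``curvature_method`` selects how κ is obtained at the stride samples:
    ``"analytic"`` reads the path's exact curvature profile (a junction
    crossed in one stride then yields jerk s²κ·f); ``"circumradius"`` runs
    the stride samples through the same three-point circumradius estimator
    used for tracking data, which is the like-for-like basis for comparing
    a measured running path against the constructed track path.

    ``distance_at_time``, when given, supplies the exact distance covered at
    each stride instant (time marching); otherwise distance is advanced by
    one stride length per step using the local speed.

    Returns a frame with ``distance_m, speed_mps, curvature_1pm,
    acc_cent_mps2, jerk_mps3`` (jerk aligned to the leading sample; trailing
    samples NaN).
    """
    if stride_frequency <= 0:
        raise ValueError("stride_frequency must be positive")
    if total_distance is None:
        total_distance = path.loop_length
    end = start_distance + total_distance

    dists = []
    if distance_at_time is not None:
        # exact time marching on the supplied motion law
        k = 0
        prev = -np.inf
        while True:
            d = float(distance_at_time(k / stride_frequency))
            if d > end + 1e-9 or d <= prev + 1e-9:
                if k > 0:
                    break
            elif d >= start_distance - 1e-9:
                dists.append(d)
            prev = d
            k += 1
            if k > 10_000_000:  # pragma: no cover - defensive
                break
        dists = np.asarray(dists, dtype=float)
    else:
        d = float(start_distance)
        out = [d]
        while True:
            v = float(np.maximum(speed_at(np.asarray(d)), 0.0))
            step = v / stride_frequency
            if step <= 1e-9:
                break
            d = d + step
            if d > end + 1e-9:
                break
            out.append(d)
        dists = np.asarray(out, dtype=float)

    speeds = np.maximum(np.asarray(speed_at(dists), dtype=float), 0.0)
    arcs = start_arclength + (dists - start_distance)

    if curvature_method == "analytic":
        kappa = np.abs(np.asarray(path.curvature_at(arcs), dtype=float))
    elif curvature_method == "circumradius":
        pts = path.point_at(arcs)
        kappa = np.full(len(dists), np.nan)
        if len(dists) >= 3:
            from .kinematics import curvature_series

            kappa = np.abs(curvature_series(pts[:, 0], pts[:, 1]))
    else:
        raise ValueError(f"unknown curvature_method: {curvature_method!r}")

    a_c = speeds**2 * kappa
    jerk = np.full(len(dists), np.nan)
    if len(dists) >= 2:
        jerk[:-1] = np.diff(a_c) * stride_frequency
    return pd.DataFrame(
        {
            "distance_m": dists,
            "speed_mps": speeds,
            "curvature_1pm": kappa,
            "acc_cent_mps2": a_c,
            "jerk_mps3": jerk,
        }
    )


def export_path_csv(path: TrackPath, file) -> None:
    """Write the path as CSV: arclength_m, x_m, y_m, curvature_1pm."""
    df = pd.DataFrame(
        {
            "arclength_m": path.arclengths,
            "x_m": path.vertices[:, 0],
            "y_m": path.vertices[:, 1],
            "curvature_1pm": path.curvature,
        }
    )
    df.to_csv(file, index=False, float_format="%.6f")
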