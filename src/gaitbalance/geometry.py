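"""Gait balance-control geometry.

Three measures of the interaction between the body center of mass (CoM) and
the base of support (BoS), evaluated at heel-strike events:

* CoM-BoS distance - shortest horizontal distance from the CoM projection to
  the BoS boundary (static balance control), cm;
* CoMv-BoS displacement - distance from the CoM projection to the BoS
  boundary measured along the instantaneous horizontal CoM velocity
  direction (dynamic balance control), cm;
* BoS area - area of the support polygon, cm^2.

The BoS is the in-contact foot outline during single support and the convex
hull of both outlines during double support.  All geometry is computed in
the ground plane, in metres internally; results are reported in cm / cm^2.
Trajectories are low-pass filtered (zero-phase fourth-order Butterworth,
8 Hz cutoff) before evaluation, the standard conditioning step for
60-Hz motion-capture data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from shapely.geometry import LineString, MultiPoint, Point
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import FilterParameterError, FlightPhaseError, GeometryError

__all__ = [
    "M_TO_CM",
    "M2_TO_CM2",
    "BalanceAtEvent",
    "lowpass_filter",
    "build_bos",
    "com_bos_distance",
    "comv_bos_displacement",
    "polygon_area",
    "evaluate_trial",
]

M_TO_CM = 100.0
M2_TO_CM2 = 1.0e4

#: velocity magnitudes below this (m/s) leave the CoMv-BoS measure undefined
VELOCITY_EPSILON = 1e-4


def lowpass_filter(
    series: np.ndarray,
    fs: float,
    cutoff: float = 8.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter along axis 0.

    Zero-phase (forward-backward) by default, which squares the magnitude
    response; ``zero_phase=False`` applies a single causal pass.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 2.0 * cutoff:
        raise FilterParameterError(
            f"sampling rate {fs} Hz must exceed twice the {cutoff} Hz cutoff"
        )
    if series.shape[0] < 3 * order:
        raise FilterParameterError(
            f"series of length {series.shape[0]} too short for order-{order} filter"
        )
    b, a = sps.butter(order, cutoff / (fs / 2.0), btype="low")
    if zero_phase:
        padlen = min(3 * (max(len(a), len(b)) - 1), series.shape[0] - 1)
        return sps.filtfilt(b, a, series, axis=0, padlen=padlen)
    return sps.lfilter(b, a, series, axis=0)


def _as_shapely(polygon) -> ShapelyPolygon:
    if isinstance(polygon, ShapelyPolygon):
        poly = polygon
    else:
        vertices = np.asarray(polygon, dtype=float)
        if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
            raise GeometryError("polygon needs >= 3 planar vertices")
        poly = ShapelyPolygon(vertices)
    if not poly.is_valid or poly.area <= 0.0:
        raise GeometryError("degenerate or self-intersecting polygon")
    return poly


def polygon_area(polygon) -> float:
    """Shoelace area of a simple polygon (vertices in m), in cm^2."""
    return _as_shapely(polygon).area * M2_TO_CM2


def build_bos(trial, frame: int) -> ShapelyPolygon:
    """Base of support at a frame: foot outline or double-support convex hull."""
    outlines = []
    for foot in (trial.left_foot, trial.right_foot):
        if foot.contact[frame]:
            outlines.append(np.asarray(foot.outline[frame], dtype=float))
    if not outlines:
        raise FlightPhaseError(f"no foot in contact at frame {frame}")
    if len(outlines) == 1:
        return _as_shapely(outlines[0])
    hull = MultiPoint([tuple(p) for p in np.vstack(outlines)]).convex_hull
    if not isinstance(hull, ShapelyPolygon):
        raise GeometryError("support points are collinear; BoS has zero area")
    return hull


def com_bos_distance(com_xy, polygon) -> tuple[float, bool]:
    """Distance (cm) from the CoM ground projection to the BoS boundary.

    Returns ``(distance_cm, inside)``; the distance is the minimum over the
    full boundary (edges included), reported unsigned either side.
    """
    poly = _as_shapely(polygon)
    point = Point(float(com_xy[0]), float(com_xy[1]))
    return poly.exterior.distance(point) * M_TO_CM, bool(poly.covers(point))


def comv_bos_displacement(com_xy, velocity_xy, polygon,
                          velocity_epsilon: float = VELOCITY_EPSILON):
    """Displacement (cm) from the CoM to the BoS boundary along the velocity.

    Casts a ray from the CoM projection along the horizontal velocity
    direction and returns the distance to its first boundary crossing.
    Returns ``(None, reason)`` when the speed is below ``velocity_epsilon``
    or the ray never meets the boundary (CoM outside, moving away).
    """
    poly = _as_shapely(polygon)
    v = np.asarray(velocity_xy, dtype=float)
    speed = float(np.hypot(v[0], v[1]))
    if speed < velocity_epsilon:
        return None, "near-zero velocity"
    u = v / speed
    p = np.asarray(com_xy, dtype=float)
    # ray long enough to traverse any support polygon
    minx, miny, maxx, maxy = poly.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny) + float(
        Point(p).distance(poly.centroid)
    ) + 1.0
    ray = LineString([tuple(p), tuple(p + reach * u)])
    hits = ray.intersection(poly.exterior)
    if hits.is_empty:
        return None, "ray does not meet the boundary"
    if hits.geom_type == "Point":
        pts = [hits]
    else:
        pts = [g for g in getattr(hits, "geoms", []) if g.geom_type == "Point"]
        for g in getattr(hits, "geoms", []):
            if g.geom_type == "LineString":  # ray grazing along an edge
                pts.extend(Point(c) for c in g.coords)
    if not pts:
        return None, "ray does not meet the boundary"
    dist_m = min(np.hypot(pt.x - p[0], pt.y - p[1]) for pt in pts)
    return dist_m * M_TO_CM, None


@dataclass
class BalanceAtEvent:
    """Balance measures at one heel-strike event."""

    frame: int
    side: str
    com_bos: float          # cm
    comv_bos: float | None  # cm; None when undefined
    bos_area: float         # cm^2
    com_inside: bool
    comv_undefined_reason: str | None = None


def _central_differences(xy: np.ndarray, fs: float) -> np.ndarray:
    return np.gradient(xy, 1.0 / fs, axis=0)


def evaluate_trial(trial, filter_on: bool = True):
    """Evaluate the three balance measures at every heel strike of a trial.

    Returns ``(events, summary)`` where ``events`` is a list of
    :class:`BalanceAtEvent` and ``summary`` is a dict with the per-trial
    means (``com_bos``, ``comv_bos``, ``bos_area``) over events with defined
    values plus ``n_events`` and ``n_comv_undefined``.
    """
    from .cohort import BalanceOutcome  # local import to avoid cycle

    if not trial.events:
        raise GeometryError("trial has no heel-strike events")
    com = np.asarray(trial.com_position, dtype=float)[:, :2]
    n = com.shape[0]
    for frame, _side in trial.events:
        if not 0 <= frame < n:
            raise IndexError(f"event frame {frame} outside series of length {n}")
    if filter_on:
        com = lowpass_filter(com, trial.sampling_rate)
    if trial.com_velocity is not None:
        vel = np.asarray(trial.com_velocity, dtype=float)[:, :2]
        if filter_on:
            vel = lowpass_filter(vel, trial.sampling_rate)
    else:
        vel = _central_differences(com, trial.sampling_rate)

    events_out: list[BalanceAtEvent] = []
    for frame, side in trial.events:
        bos = build_bos(trial, frame)
        d, inside = com_bos_distance(com[frame], bos)
        v, reason = comv_bos_displacement(com[frame], vel[frame], bos)
        events_out.append(
            BalanceAtEvent(
                frame=frame, side=side, com_bos=d, comv_bos=v,
                bos_area=bos.area * M2_TO_CM2, com_inside=inside,
                comv_undefined_reason=reason,
            )
        )

    comv_defined = [e.comv_bos for e in events_out if e.comv_bos is not None]
    summary = {
        "com_bos": float(np.mean([e.com_bos for e in events_out])),
        "comv_bos": float(np.mean(comv_defined)) if comv_defined else None,
        "bos_area": float(np.mean([e.bos_area for e in events_out])),
        "n_events": len(events_out),
        "n_comv_undefined": len(events_out) - len(comv_defined),
    }
    outcome = (
        BalanceOutcome(summary["com_bos"], summary["comv_bos"], summary["bos_area"])
        if summary["comv_bos"] is not None
        else None
    )
    return events_out, summary, outcome
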