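"""Synthetic gait trials realizing prescribed balance outcomes.

A trial is built by inverse design: alternating left/right footprints are
laid out so that the double-support convex hull at each heel strike has the
requested BoS area; the CoM is then threaded through the trial on a smooth
spline that passes, at every heel-strike frame, through a point whose
distance to the hull boundary equals the requested CoM-BoS distance, with a
velocity direction whose ray-cast distance to the boundary equals the
requested CoMv-BoS displacement.  Geometry evaluated on the resulting trial
therefore recovers the requested outcome up to spline/filtering effects and
a small configurable path noise.

Footprints are rectangle-with-rounded-toe templates; foot length defaults to
0.152 x body height, a standard anthropometric ratio.  At initial contact
the leading foot touches the ground with its heel only, so during the
double-support window that follows a heel strike its outline is the rear
(heel) segment of the template; it becomes the full outline once the
trailing foot toes off.  This matches how dynamic BoS models treat the
heel-contact phase and yields double-support areas in the physiological
range of a few hundred cm^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline
from shapely.affinity import translate
from shapely.geometry import Point
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import GenerationError, SchemaError
from .geometry import (
    M2_TO_CM2,
    M_TO_CM,
    com_bos_distance,
    comv_bos_displacement,
    lowpass_filter,
)

__all__ = [
    "FootTimeSeries",
    "GaitTrial",
    "TrialParams",
    "footprint_template",
    "generate_trial",
    "write_trial",
    "read_trial",
]


@dataclass
class FootTimeSeries:
    """Per-frame outline vertices (m) and ground-contact flag for one foot."""

    outline: list  # list of (k, 2) arrays
    contact: np.ndarray  # bool, per frame


@dataclass
class GaitTrial:
    """Time series of CoM kinematics, foot outlines and heel-strike events."""

    sampling_rate: float  # Hz
    com_position: np.ndarray  # (n, 3) m
    left_foot: FootTimeSeries
    right_foot: FootTimeSeries
    events: list  # [(frame, side), ...] strictly increasing frames
    com_velocity: np.ndarray | None = None  # (n, 2) m/s, optional


@dataclass
class TrialParams:
    """Gait layout parameters (SI units)."""

    body_height: float = 1.65       # m; elderly-adult default
    foot_length_ratio: float = 0.152  # foot length / body height
    foot_width_ratio: float = 0.36    # foot width / foot length
    heel_frac: float = 0.45         # fraction of foot length down at heel strike
    step_width: float = 0.08        # lateral distance between foot centers, m
    step_time: float = 0.55         # s per step
    sampling_rate: float = 60.0     # Hz, motion-capture marker rate
    n_events: int = 6               # heel strikes evaluated (>= 4)
    double_support_frac: float = 0.2  # fraction of step time both feet down
    com_height_ratio: float = 0.55  # CoM height / body height
    path_noise_sd: float = 0.001    # m, smooth low-frequency CoM wander
    toe_arc_points: int = 7


def footprint_template(params: TrialParams) -> ShapelyPolygon:
    """Foot outline in its local frame: heel at origin, toes toward +y."""
    length = params.foot_length_ratio * params.body_height
    width = params.foot_width_ratio * length
    r = width / 2.0
    straight = length - r
    pts = [(-r, 0.0), (r, 0.0), (r, straight)]
    for ang in np.linspace(0.0, math.pi, params.toe_arc_points + 2)[1:-1]:
        pts.append((r * math.cos(ang), straight + r * math.sin(ang)))
    pts.append((-r, straight))
    return ShapelyPolygon(pts)


def heel_template(params: TrialParams) -> ShapelyPolygon:
    """Heel segment of the footprint: the rear ``heel_frac`` of its length."""
    length = params.foot_length_ratio * params.body_height
    width = params.foot_width_ratio * length
    r = width / 2.0
    h = params.heel_frac * length
    return ShapelyPolygon([(-r, 0.0), (r, 0.0), (r, h), (-r, h)])


def _double_support_hull(foot: ShapelyPolygon, heel: ShapelyPolygon,
                         step_width: float, step_length: float) -> ShapelyPolygon:
    """Hull of a full trailing foot at (-w/2, 0) and leading heel at (+w/2, S)."""
    trailing = translate(foot, xoff=-step_width / 2.0)
    leading = translate(heel, xoff=+step_width / 2.0, yoff=step_length)
    return trailing.union(leading).convex_hull


def _solve_step_length(area_cm2: float, foot: ShapelyPolygon,
                       heel: ShapelyPolygon, step_width: float) -> float:
    """Step length whose double-support hull has the requested area."""
    target = area_cm2 / M2_TO_CM2
    lo, hi = 0.02, 1.2
    a_lo = _double_support_hull(foot, heel, step_width, lo).area
    a_hi = _double_support_hull(foot, heel, step_width, hi).area
    if target < a_lo:
        raise GenerationError(
            f"bos_area {area_cm2:.0f} cm^2 below the minimum hull area "
            f"{a_lo * M2_TO_CM2:.0f} cm^2 of two adjacent footprints"
        )
    if target > a_hi:
        raise GenerationError(
            f"bos_area {area_cm2:.0f} cm^2 would need a step longer than {hi} m"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _double_support_hull(foot, heel, step_width, mid).area < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ray_distance(q: np.ndarray, theta: float, hull: ShapelyPolygon) -> float:
    d, _ = comv_bos_displacement(q, (math.cos(theta), math.sin(theta)), hull,
                                 velocity_epsilon=0.0)
    return math.inf if d is None else d


def _solve_event_pose(hull: ShapelyPolygon, com_bos_cm: float,
                      comv_bos_cm: float) -> tuple[np.ndarray, float]:
    """CoM point and heading angle realizing both distance measures.

    The point is sought on the boundary of the hull eroded by the CoM-BoS
    distance (every such point is exactly that far from the boundary of a
    convex hull); the heading is found by bisecting the continuous
    angle -> ray-distance map.  Rear points and forward headings are
    preferred so the pose resembles gait.
    """
    d_m = com_bos_cm / M_TO_CM
    eroded = hull.buffer(-d_m)
    if eroded.is_empty or eroded.area <= 0.0:
        raise GenerationError(
            f"com_bos {com_bos_cm:.1f} cm exceeds the deepest interior point "
            f"of a BoS of area {hull.area * M2_TO_CM2:.0f} cm^2"
        )
    if comv_bos_cm < com_bos_cm:
        raise GenerationError(
            f"comv_bos {comv_bos_cm:.1f} cm cannot undercut com_bos "
            f"{com_bos_cm:.1f} cm"
        )
    ring = eroded.exterior
    n_pts, n_ang = 64, 48
    fractions = np.linspace(0.0, 1.0, n_pts, endpoint=False)
    candidates = [np.asarray(ring.interpolate(f, normalized=True).coords[0])
                  for f in fractions]
    candidates.sort(key=lambda p: p[1])  # rear (small y) first

    forward = math.pi / 2.0  # walking direction is +y
    cones = [(forward - 1.4, forward + 1.4), (-math.pi, math.pi)]
    for lo_ang, hi_ang in cones:
        for q in candidates:
            thetas = np.linspace(lo_ang, hi_ang, n_ang)
            dists = np.array([_ray_distance(q, t, hull) for t in thetas])
            for i in range(len(thetas) - 1):
                f0, f1 = dists[i] - comv_bos_cm, dists[i + 1] - comv_bos_cm
                if not (np.isfinite(f0) and np.isfinite(f1)) or f0 * f1 > 0:
                    continue
                a, b = thetas[i], thetas[i + 1]
                fa = f0
                for _ in range(60):
                    m = 0.5 * (a + b)
                    fm = _ray_distance(q, m, hull) - comv_bos_cm
                    if fa * fm <= 0:
                        b = m
                    else:
                        a, fa = m, fm
                return q, 0.5 * (a + b)
    raise GenerationError(
        f"no heading achieves comv_bos {comv_bos_cm:.1f} cm from any point at "
        f"com_bos {com_bos_cm:.1f} cm inside a BoS of area "
        f"{hull.area * M2_TO_CM2:.0f} cm^2"
    )


def _solve_layout(outcome, params: TrialParams):
    """Footprints, stance width, step length and event pose for an outcome.

    Subjects with small BoS areas get proportionally scaled (smaller) feet
    and stance; subjects whose CoM-BoS distance needs a deeper support get a
    wider stance.  Raises :class:`GenerationError` when no layout works.
    """
    from shapely.affinity import scale as _scale

    base_foot = footprint_template(params)
    base_heel = heel_template(params)
    target_m2 = outcome.bos_area / M2_TO_CM2
    last_err: GenerationError | None = None
    for widen in (1.0, 1.35, 1.75):
        foot, heel = base_foot, base_heel
        w = params.step_width * widen
        a_min = _double_support_hull(foot, heel, w, 0.02).area
        if target_m2 < a_min:
            c = math.sqrt(target_m2 / a_min) * 0.97
            if c < 0.45:
                raise GenerationError(
                    f"bos_area {outcome.bos_area:.0f} cm^2 implies implausibly "
                    f"small feet (scale factor {c:.2f})"
                )
            foot = _scale(foot, xfact=c, yfact=c, origin=(0, 0))
            heel = _scale(heel, xfact=c, yfact=c, origin=(0, 0))
            w *= c
        try:
            step_len = _solve_step_length(outcome.bos_area, foot, heel, w)
            hull = _double_support_hull(foot, heel, w, step_len)
            q, theta = _solve_event_pose(hull, outcome.com_bos, outcome.comv_bos)
            return foot, heel, w, step_len, q, theta
        except GenerationError as err:
            last_err = err
    raise last_err


def _smooth_noise(n: int, fs: float, sd: float, rng: np.random.Generator):
    """Band-limited (<1.5 Hz) random wander with the given pointwise SD."""
    if sd <= 0.0:
        return np.zeros((n, 2))
    t = np.arange(n) / fs
    out = np.zeros((n, 2))
    freqs = rng.uniform(0.2, 1.5, size=(4, 2))
    phases = rng.uniform(0.0, 2 * math.pi, size=(4, 2))
    amps = rng.uniform(0.5, 1.0, size=(4, 2))
    for k in range(4):
        out += amps[k] * np.sin(2 * math.pi * freqs[k] * t[:, None] + phases[k])
    out *= sd / out.std(axis=0, keepdims=True)
    return out


def generate_trial(subject, outcome, trial_params: TrialParams | None = None,
                   seed: int = 0) -> GaitTrial:
    """Build a gait trial whose evaluated balance measures match ``outcome``.

    ``subject`` is accepted for interface symmetry with the cohort generator
    (anthropometrics come from ``trial_params``); ``outcome`` carries the
    target CoM-BoS (cm), CoMv-BoS (cm) and BoS area (cm^2).
    """
    params = trial_params or TrialParams()
    if params.n_events < 4:
        raise GenerationError("a trial needs at least 4 heel-strike events")
    rng = np.random.default_rng(seed)
    foot, heel, step_width, step_len, q, theta = _solve_layout(outcome, params)

    fs, T = params.sampling_rate, params.step_time
    n_ev = params.n_events
    n_frames = int(round((n_ev + 0.6) * T * fs)) + 1
    times = np.arange(n_frames) / fs

    # foot placements k = 0..n_ev: alternating sides, advancing step_len
    placements = []
    for k in range(n_ev + 1):
        side = "left" if k % 2 == 0 else "right"
        x = -step_width / 2.0 if side == "left" else +step_width / 2.0
        placements.append((side, np.array([x, k * step_len])))

    # heel-strike events k = 1..n_ev at t = k*T; the hull of feet (k-1, k)
    # is the prototype hull translated forward (mirrored for left strikes)
    event_frames = [int(round(k * T * fs)) for k in range(1, n_ev + 1)]
    speed = step_len / T
    events, knots_t, knots_p, target_angles = [], [], [], []
    for idx, k in enumerate(range(1, n_ev + 1)):
        frame = event_frames[idx]
        side = placements[k][0]
        mirror = -1.0 if side == "left" else 1.0
        p = np.array([mirror * q[0], q[1] + (k - 1) * step_len])
        ang = math.atan2(math.sin(theta), mirror * math.cos(theta))
        knots_t.append(frame / fs)
        knots_p.append(p)
        target_angles.append(ang)
        events.append((frame, side))

    # The measured heading at an event comes from central differences of the
    # *filtered* trajectory, which deviates slightly from the spline's knot
    # tangent.  Iteratively rotate the knot velocities so the measured
    # heading converges onto the solved pose heading.
    angles = list(target_angles)
    com_spline = None
    for _ in range(6):
        knots_v = [speed * np.array([math.cos(a), math.sin(a)]) for a in angles]
        t0, tN = 0.0, times[-1]
        full_t = np.asarray([t0] + knots_t + [tN])
        full_p = np.vstack(
            [knots_p[0] - knots_v[0] * (knots_t[0] - t0)]
            + knots_p
            + [knots_p[-1] + knots_v[-1] * (tN - knots_t[-1])]
        )
        full_v = np.vstack([knots_v[0]] + knots_v + [knots_v[-1]])
        spline = CubicHermiteSpline(full_t, full_p, full_v, axis=0)
        com_spline = spline(times)
        filtered = lowpass_filter(com_spline, fs)
        vel = np.gradient(filtered, 1.0 / fs, axis=0)
        worst = 0.0
        for i, frame in enumerate(event_frames):
            measured = math.atan2(vel[frame, 1], vel[frame, 0])
            err = math.remainder(target_angles[i] - measured, 2 * math.pi)
            angles[i] += err
            worst = max(worst, abs(err))
        if worst < 1e-5:
            break
    com_xy = com_spline + _smooth_noise(n_frames, fs, params.path_noise_sd, rng)
    com_z = params.com_height_ratio * params.body_height + 0.02 * np.sin(
        2 * math.pi * times / T
    )
    com = np.column_stack([com_xy, com_z])

    feet = {
        "left": _foot_series(params, foot, heel, placements, "left", times, T),
        "right": _foot_series(params, foot, heel, placements, "right", times, T),
    }

    return GaitTrial(
        sampling_rate=fs, com_position=com,
        left_foot=feet["left"], right_foot=feet["right"], events=events,
    )


def _foot_series(params: TrialParams, foot: ShapelyPolygon,
                 heel: ShapelyPolygon, placements, side: str,
                 times: np.ndarray, T: float):
    """Outline/contact time series for one foot across its placements.

    A placement that begins with a heel strike (every one after the first)
    contributes the heel-segment outline during the initial double-support
    window and the full outline afterwards.
    """
    own = [(k, pos) for k, (s, pos) in enumerate(placements) if s == side]
    full = np.asarray(foot.exterior.coords[:-1], dtype=float)
    heel_v = np.asarray(heel.exterior.coords[:-1], dtype=float)
    n = len(times)
    contact = np.zeros(n, dtype=bool)
    centers = np.zeros((n, 2))
    heel_phase = np.zeros(n, dtype=bool)
    for j, (k, pos) in enumerate(own):
        t_on = k * T if k > 0 else 0.0
        ds_end = k * T + params.double_support_frac * T
        t_off = (k + 1) * T + params.double_support_frac * T
        mask = (times >= t_on - 1e-9) & (times <= t_off + 1e-9)
        if j == len(own) - 1:
            mask = times >= t_on - 1e-9
        contact |= mask
        centers[mask] = pos
        if k > 0:
            heel_phase |= mask & (times <= ds_end + 1e-9)
        if j + 1 < len(own):  # swing: interpolate toward the next placement
            k2, pos2 = own[j + 1]
            t_on2 = k2 * T
            swing = (times > t_off) & (times < t_on2)
            if swing.any():
                frac = (times[swing] - t_off) / (t_on2 - t_off)
                centers[swing] = pos + frac[:, None] * (pos2 - pos)
    if not contact[0] and own:
        centers[: np.argmax(contact)] = own[0][1]
    outlines = [
        (heel_v if heel_phase[i] else full) + centers[i] for i in range(n)
    ]
    return FootTimeSeries(outline=outlines, contact=contact)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def write_trial(trial: GaitTrial, path) -> None:
    """Write a trial to JSON (documented schema, SI units)."""
    payload = {
        "sampling_rate": trial.sampling_rate,
        "com_position": np.asarray(trial.com_position).tolist(),
        "events": [[int(f), s] for f, s in trial.events],
    }
    for name, foot in (("left_foot", trial.left_foot), ("right_foot", trial.right_foot)):
        payload[name] = {
            "outline": [np.asarray(o).tolist() for o in foot.outline],
            "contact": np.asarray(foot.contact).astype(bool).tolist(),
        }
    if trial.com_velocity is not None:
        payload["com_velocity"] = np.asarray(trial.com_velocity).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_trial(path) -> GaitTrial:
    with open(path) as fh:
        payload = json.load(fh)
    required = {"sampling_rate", "com_position", "left_foot", "right_foot", "events"}
    missing = required - payload.keys()
    if missing:
        raise SchemaError(f"trial JSON missing keys: {sorted(missing)}")
    feet = {}
    for name in ("left_foot", "right_foot"):
        foot = payload[name]
        feet[name] = FootTimeSeries(
            outline=[np.asarray(o, dtype=float) for o in foot["outline"]],
            contact=np.asarray(foot["contact"], dtype=bool),
        )
    vel = payload.get("com_velocity")
    return GaitTrial(
        sampling_rate=float(payload["sampling_rate"]),
        com_position=np.asarray(payload["com_position"], dtype=float),
        left_foot=feet["left_foot"],
        right_foot=feet["right_foot"],
        events=[(int(f), str(s)) for f, s in payload["events"]],
        com_velocity=None if vel is None else np.asarray(vel, dtype=float),
    )
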