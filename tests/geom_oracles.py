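"""Brute-force geometry oracles, independent of the package implementation.

Everything here is plain numpy: even-odd point-in-polygon, dense boundary
sampling for minimum distance, ray marching for directed distance, O(n^3)
convex hull, and fan-triangulation area.  Deliberately naive and slow.
"""

import numpy as np


def point_in_polygon(point, vertices) -> bool:
    """Even-odd crossing test."""
    return bool(points_in_polygon(np.asarray(point, dtype=float)[None, :], vertices)[0])


def points_in_polygon(points, vertices) -> np.ndarray:
    """Vectorized even-odd test for an (n, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    crosses = (y1[None, :] > y) != (y2[None, :] > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
    hits = crosses & (x < xin)
    return (hits.sum(axis=1) % 2).astype(bool)


def boundary_samples(vertices, n_samples: int) -> np.ndarray:
    """Uniformly spaced points along the polygon boundary."""
    v = np.asarray(vertices, dtype=float)
    seg = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    s = np.linspace(0.0, cum[-1], n_samples, endpoint=False)
    idx = np.searchsorted(cum, s, side="right") - 1
    frac = (s - cum[idx]) / lengths[idx]
    return v[idx] + frac[:, None] * seg[idx]


def min_distance_dense(point, vertices, n_samples: int = 100_000) -> float:
    """Minimum distance to the boundary by dense sampling, in metres."""
    samples = boundary_samples(vertices, n_samples)
    d = samples - np.asarray(point, dtype=float)
    return float(np.min(np.hypot(d[:, 0], d[:, 1])))


def ray_march_distance(point, direction, vertices, step: float = 1e-5,
                       max_len: float = 4.0):
    """Distance along `direction` to the first boundary crossing, in metres.

    Marches from the point in fixed steps until the inside/outside state
    flips, then bisects the bracketing step.  Returns None if no crossing
    occurs within max_len.
    """
    p = np.asarray(point, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.hypot(u[0], u[1])
    n = int(max_len / step)
    ts = step * np.arange(n + 1)
    pts = p[None, :] + ts[:, None] * u[None, :]
    inside = points_in_polygon(pts, vertices)
    flips = np.nonzero(inside[:-1] != inside[1:])[0]
    if flips.size == 0:
        return None
    i = int(flips[0])
    lo, hi = ts[i], ts[i + 1]
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if points_in_polygon((p + mid * u)[None, :], vertices)[0] == inside[i]:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def brute_force_hull(points) -> np.ndarray:
    """O(n^3) convex hull: keep points that are vertices of the hull.

    An edge (i, j) is on the hull iff all other points lie on one side;
    vertices are collected and ordered by angle about the centroid.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = pts[j] - pts[i]
            cross = e[0] * (pts[:, 1] - pts[i, 1]) - e[1] * (pts[:, 0] - pts[i, 0])
            others = np.delete(cross, [i, j])
            if np.all(others >= -1e-12) or np.all(others <= 1e-12):
                on_hull.add(i)
                on_hull.add(j)
    hull = pts[sorted(on_hull)]
    c = hull.mean(axis=0)
    ang = np.arctan2(hull[:, 1] - c[1], hull[:, 0] - c[0])
    return hull[np.argsort(ang)]


def shoelace_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def fan_triangulation_area(vertices) -> float:
    """Area of a convex polygon as a fan of triangles from vertex 0."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        total += 0.5 * abs(
            (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        )
    return total


def random_convex_polygon(rng, n_points: int = 8, radius: float = 0.3,
                          center=(0.0, 0.0)):
    """Random convex polygon: hull of points on a wobbly circle."""
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n_points))
    radii = rng.uniform(0.4 * radius, radius, n_points)
    pts = np.column_stack([
        center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)
    ])
    return brute_force_hull(pts)


def random_interior_point(rng, vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    while True:
        p = rng.uniform(lo, hi)
        if points_in_polygon(p[None, :], v)[0]:
            return p
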