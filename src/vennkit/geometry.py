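"""Plane-geometry primitives: even-odd containment and segment tests.

The even-odd (crossing-number) rule is the membership definition used
throughout the layouts: a point is inside a shape when a horizontal ray
from it crosses the shape's boundary an odd number of times, counted over
all of the shape's rings.  This matches the SVG ``evenodd`` fill rule, so a
rendered shape and its computed membership always agree.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Point = tuple[float, float]


def close_ring(ring: np.ndarray) -> np.ndarray:
    """Return ``ring`` with the first vertex repeated at the end."""
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
        raise ValueError("a ring needs at least three (x, y) vertices")
    if not np.array_equal(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[:1]])
    return ring


def ray_crossings(points: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Crossing parity of a rightward horizontal ray from each point.

    ``points`` is ``(m, 2)``; ``ring`` is a closed ring.  Returns a boolean
    array: True where the crossing count is odd (point inside the ring).
    Points are processed in chunks to bound the broadcast memory.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ring = close_ring(ring)
    x1, y1 = ring[:-1, 0], ring[:-1, 1]
    x2, y2 = ring[1:, 0], ring[1:, 1]
    keep = y1 != y2  # horizontal edges never cross a horizontal ray
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    inside = np.zeros(len(pts), dtype=bool)
    chunk = max(1, int(4e6 // max(len(x1), 1)))
    for start in range(0, len(pts), chunk):
        px = pts[start : start + chunk, 0][:, None]
        py = pts[start : start + chunk, 1][:, None]
        straddle = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        crossing = straddle & (px < x_at)
        inside[start : start + chunk] = crossing.sum(axis=1) % 2 == 1
    return inside


def points_in_rings(points: np.ndarray, rings: Iterable[np.ndarray]) -> np.ndarray:
    """Even-odd membership of each point in a multi-ring shape.

    Total crossing parity over all rings: a shell ring plus a hole ring
    yields an annulus, matching SVG's evenodd fill.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.zeros(len(pts), dtype=bool)
    for ring in rings:
        inside ^= ray_crossings(pts, ring)
    return inside


def point_in_rings(point: Point, rings: Iterable[np.ndarray]) -> bool:
    return bool(points_in_rings(np.asarray([point]), rings)[0])


def _orient(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def segments_intersect(
    a1: Point, a2: Point, b1: Point, b2: Point, *, strict: bool = True
) -> bool:
    """Whether segments a1-a2 and b1-b2 intersect.

    With ``strict`` (default) only proper crossings count: shared endpoints
    and touching configurations are ignored, which is what leader-line
    overlap checks need.
    """
    a1, a2, b1, b2 = (np.asarray(p, dtype=float) for p in (a1, a2, b1, b2))
    d1 = _orient(b1, b2, a1)
    d2 = _orient(b1, b2, a2)
    d3 = _orient(a1, a2, b1)
    d4 = _orient(a1, a2, b2)
    if strict:
        return (d1 * d2 < 0) and (d3 * d4 < 0)
    if (d1 * d2 < 0) and (d3 * d4 < 0):
        return True

    def on_seg(p, q, r):  # r collinear with p-q, within bbox
        return (
            min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
            and min(p[1], q[1]) <= r[1] <= max(p[1], q[1])
        )

    return (
        (d1 == 0 and on_seg(b1, b2, a1))
        or (d2 == 0 and on_seg(b1, b2, a2))
        or (d3 == 0 and on_seg(a1, a2, b1))
        or (d4 == 0 and on_seg(a1, a2, b2))
    )


def circle_ring(
    center: Point, radius: float, n_points: int = 256
) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    return close_ring(
        np.column_stack(
            [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
        )
    )


def ellipse_ring(
    center: Point,
    semi_x: float,
    semi_y: float,
    angle_deg: float = 0.0,
    n_points: int = 256,
) -> np.ndarray:
    """Rotated ellipse; the rotation is counter-clockwise in x-right/y-down
    screen coordinates for positive ``angle_deg`` measured as in SVG."""
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    x = semi_x * np.cos(theta)
    y = semi_y * np.sin(theta)
    phi = np.deg2rad(angle_deg)
    xr = x * np.cos(phi) - y * np.sin(phi)
    yr = x * np.sin(phi) + y * np.cos(phi)
    return close_ring(np.column_stack([center[0] + xr, center[1] + yr]))


def polygon_ring(vertices: Sequence[Point]) -> np.ndarray:
    return close_ring(np.asarray(vertices, dtype=float))


def rect_ring(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return polygon_ring([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
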