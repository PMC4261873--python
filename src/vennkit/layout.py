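"""Diagram geometry for classical and Edwards-Venn layouts (2-6 sets).

A layout is a list of closed set shapes on an abstract canvas (x right,
y down, SVG viewBox semantics) plus, for every exclusive region, an anchor
point that lies inside exactly the member shapes of that region under the
even-odd rule.  Correctness is topological: a template is valid when all
``2**n - 1`` anchors pass that exact-membership test (``validate_layout``),
not when it matches any particular reference drawing pixel for pixel.

Classic templates use overlapping circles (2-3 sets), the familiar ellipse
arrangements (4-5 sets) and a six-triangle arrangement (6 sets).  The
Edwards construction uses two half-plane rectangles, a central circle, and
serpentine ("cogwheel") bands whose centre radius oscillates in and out of
the circle with ``2**(k-3)`` teeth for the k-th set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from . import geometry as geo
from .io_formats import LABELS
from .setcore import RegionTable, canonical_regions, region_sort_key

CANVAS = 700.0
MODE_CLASSIC = "classic"
MODE_EDWARDS = "edwards"

# glyph width of a digit as a fraction of the font size (sans-serif estimate)
GLYPH_WIDTH_FRACTION = 0.62
DEFAULT_FONT_SIZE = 13.0
# regions smaller than this (square canvas units) qualify for callouts
CALLOUT_AREA_THRESHOLD = 900.0

# Edwards construction constants (abstract canvas units)
_ED_MARGIN = 54.0  # chart frame inset; names/callouts live outside it
_ED_RADIUS = 160.0  # central circle radius
_ED_AMPLITUDE = 0.28  # radial oscillation of band centre, fraction of radius
_ED_SQUARENESS = 6.0  # tanh sharpening of the square-wave teeth
_ED_HALF_WIDTHS = {4: 40.0, 5: 24.0, 6: 11.0}  # nested band half-widths
_ED_BAND_POINTS = 1024


@dataclass(frozen=True)
class SetShape:
    """One set's closed outline: a shell ring plus optional hole rings."""

    label: str
    rings: tuple[np.ndarray, ...]

    def as_polygon(self) -> Polygon:
        return Polygon(self.rings[0], [r for r in self.rings[1:]])


@dataclass(frozen=True)
class Callout:
    """External count label for a region too small to label in place."""

    region: str
    label_point: tuple[float, float]
    line: tuple[tuple[float, float], ...]  # anchor -> label leader polyline


@dataclass(frozen=True)
class LayoutSpec:
    mode: str
    n: int
    width: float
    height: float
    shapes: tuple[SetShape, ...]
    anchors: dict[str, tuple[float, float]]
    budgets: dict[str, int]
    areas: dict[str, float]
    name_points: dict[str, tuple[float, float]]


def _region_polygon(polys: dict[str, Polygon], key: str) -> Polygon | None:
    geom = polys[key[0]]
    for lab in key[1:]:
        geom = geom.intersection(polys[lab])
    others = [polys[lab] for lab in polys if lab not in key]
    if others:
        geom = geom.difference(unary_union(others))
    if geom.is_empty:
        return None
    if isinstance(geom, MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    if not isinstance(geom, Polygon) or geom.area <= 0:
        return None
    return geom


def compose_layout(
    mode: str,
    shapes: Sequence[SetShape],
    width: float = CANVAS,
    height: float = CANVAS,
    font_size: float = DEFAULT_FONT_SIZE,
) -> LayoutSpec:
    """Assemble a layout from set shapes: solve anchors and budgets.

    Anchors are centres of each region's maximum inscribed circle, so they
    sit as deep inside the region as possible; the character budget is how
    many digit glyphs fit across that circle.  Regions whose geometric
    intersection is empty get no anchor (``validate_layout`` reports them).
    """
    shapes = tuple(shapes)
    n = len(shapes)
    polys = {s.label: s.as_polygon().buffer(0) for s in shapes}
    anchors: dict[str, tuple[float, float]] = {}
    budgets: dict[str, int] = {}
    areas: dict[str, float] = {}
    for key in canonical_regions([s.label for s in shapes]):
        region = _region_polygon(polys, key)
        if region is None:
            continue
        radial = shapely.maximum_inscribed_circle(region, 0.2)
        cx, cy = radial.coords[0]
        radius = radial.length
        anchors[key] = (float(cx), float(cy))
        budgets[key] = int(
            (2.0 * radius * 0.85) // (GLYPH_WIDTH_FRACTION * font_size)
        )
        areas[key] = float(region.area)
    name_points = _name_points(shapes, width, height)
    return LayoutSpec(
        mode=mode,
        n=n,
        width=width,
        height=height,
        shapes=shapes,
        anchors=anchors,
        budgets=budgets,
        areas=areas,
        name_points=name_points,
    )


def _border_point(
    width: float, height: float, angle: float, inset: float
) -> tuple[float, float]:
    """Point where the ray from the canvas centre at ``angle`` meets the
    rectangle inset from the canvas border."""
    cx, cy = width / 2.0, height / 2.0
    dx, dy = math.cos(angle), math.sin(angle)
    tx = (cx - inset) / abs(dx) if dx else math.inf
    ty = (cy - inset) / abs(dy) if dy else math.inf
    t = min(tx, ty)
    return (cx + t * dx, cy + t * dy)


def _name_points(
    shapes: Sequence[SetShape], width: float, height: float
) -> dict[str, tuple[float, float]]:
    cx, cy = width / 2.0, height / 2.0
    points = {}
    for i, shape in enumerate(shapes):
        gx, gy = shape.as_polygon().buffer(0).centroid.coords[0]
        dx, dy = gx - cx, gy - cy
        if math.hypot(dx, dy) < 20.0:
            # centred shapes (circle, serpentine bands): fan out by index
            angle = -3.0 * math.pi / 4.0 + i * 0.5
        else:
            angle = math.atan2(dy, dx)
        points[shape.label] = _border_point(width, height, angle, 30.0)
    return points


def point_in_region(layout: LayoutSpec, point: tuple[float, float]) -> str | None:
    """Label set of every shape containing ``point`` under the even-odd
    rule, as a canonical region key; ``None`` when the point is outside
    every shape."""
    labels = [
        s.label for s in layout.shapes if geo.point_in_rings(point, s.rings)
    ]
    return "".join(sorted(labels)) or None


def points_region_keys(layout: LayoutSpec, points: np.ndarray) -> list[str | None]:
    """Vectorised :func:`point_in_region` for many points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    per_shape = {
        s.label: geo.points_in_rings(pts, s.rings) for s in layout.shapes
    }
    keys: list[str | None] = []
    for i in range(len(pts)):
        key = "".join(lab for lab in sorted(per_shape) if per_shape[lab][i])
        keys.append(key or None)
    return keys


def validate_layout(layout: LayoutSpec) -> list[str]:
    """Check the layout's topology; an empty report means valid.

    Verifies that every ring is closed, that every one of the ``2**n - 1``
    regions has an anchor, and that each anchor lies inside exactly the
    member shapes of its region (even-odd membership).
    """
    report = []
    for shape in layout.shapes:
        for ring in shape.rings:
            if not np.array_equal(ring[0], ring[-1]):
                report.append(f"shape {shape.label}: ring is not closed")
    for key in canonical_regions([s.label for s in layout.shapes]):
        anchor = layout.anchors.get(key)
        if anchor is None:
            report.append(f"region {key}: no anchor (empty region)")
            continue
        found = point_in_region(layout, anchor)
        if found != key:
            report.append(
                f"region {key}: anchor {anchor} falls in region {found}"
            )
    return report


def _digits(value: float) -> int:
    text = f"{value:g}"
    return len(text)


def plan_callouts(
    layout: LayoutSpec,
    table: RegionTable,
    font_size: float = DEFAULT_FONT_SIZE,
    area_threshold: float = CALLOUT_AREA_THRESHOLD,
) -> list[Callout]:
    """Plan external labels for regions whose count cannot fit in place.

    A region gets a callout when its count needs more characters than the
    region's in-place budget and the region is small (below the area
    threshold).  Labels are placed on a rectangle just inside the canvas
    border, ordered by the angular position of their anchors; leader lines
    run straight from anchor to label and are repaired (by swapping label
    slots) until pairwise non-crossing.
    """
    cx, cy = layout.width / 2.0, layout.height / 2.0
    candidates = []
    for key in sorted(layout.anchors, key=region_sort_key):
        count = table.counts.get(key)
        if count is None:
            continue
        if _digits(count) > layout.budgets.get(key, 0) and (
            layout.areas.get(key, 0.0) < area_threshold
        ):
            candidates.append(key)
    if not candidates:
        return []
    angles = {
        key: math.atan2(layout.anchors[key][1] - cy, layout.anchors[key][0] - cx)
        for key in candidates
    }
    order = sorted(candidates, key=lambda k: (angles[k], k))
    # spread label angles so adjacent labels do not collide
    min_gap = min(0.16, 2 * math.pi / max(len(order), 1))
    slots = [angles[k] for k in order]
    for i in range(1, len(slots)):
        if slots[i] - slots[i - 1] < min_gap:
            slots[i] = slots[i - 1] + min_gap
    label_points = [
        _border_point(layout.width, layout.height, a, 30.0) for a in slots
    ]
    # untangle crossing leader lines by swapping label slots
    for _ in range(len(order) ** 2 + 1):
        crossed = False
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                if geo.segments_intersect(
                    layout.anchors[order[i]],
                    label_points[i],
                    layout.anchors[order[j]],
                    label_points[j],
                ):
                    label_points[i], label_points[j] = (
                        label_points[j],
                        label_points[i],
                    )
                    crossed = True
        if not crossed:
            break
    return [
        Callout(
            region=key,
            label_point=pt,
            line=(layout.anchors[key], pt),
        )
        for key, pt in zip(order, label_points)
    ]


# ---------------------------------------------------------------------------
# classic templates
# ---------------------------------------------------------------------------

# The 4- and 5-set ellipse parameters and the 6-set triangle vertices below
# are the widely used public-domain template coordinates for non-symmetric
# Venn diagrams (unit square, y up); they are rescaled to the canvas and
# checked by validate_layout in the test suite.
_ELLIPSES_4 = [  # (cx, cy, width, height, rotation degrees), unit square
    (0.350, 0.400, 0.72, 0.45, 140.0),
    (0.450, 0.500, 0.72, 0.45, 140.0),
    (0.544, 0.500, 0.72, 0.45, 40.0),
    (0.644, 0.400, 0.72, 0.45, 40.0),
]
_ELLIPSES_5 = [
    (0.428, 0.449, 0.87, 0.50, 155.0),
    (0.469, 0.543, 0.87, 0.50, 82.0),
    (0.558, 0.523, 0.87, 0.50, 10.0),
    (0.578, 0.432, 0.87, 0.50, 118.0),
    (0.489, 0.383, 0.87, 0.50, 46.0),
]
_TRIANGLES_6 = [  # (x1, y1, x2, y2, x3, y3), unit square
    (0.637, 0.921, 0.649, 0.274, 0.188, 0.667),
    (0.981, 0.769, 0.335, 0.191, 0.393, 0.671),
    (0.941, 0.397, 0.292, 0.475, 0.456, 0.747),
    (0.662, 0.119, 0.316, 0.548, 0.662, 0.700),
    (0.309, 0.081, 0.374, 0.718, 0.681, 0.488),
    (0.016, 0.626, 0.726, 0.687, 0.522, 0.327),
]


def _to_canvas(x: float, y: float, scale: float = CANVAS) -> tuple[float, float]:
    """Unit square (y up) -> canvas (y down)."""
    return (x * scale, (1.0 - y) * scale)


def _classic_shapes(n: int) -> list[SetShape]:
    c = CANVAS / 2.0
    if n == 2:
        r = 150.0
        centers = [(c - 80.0, c), (c + 80.0, c)]
        return [
            SetShape(LABELS[i], (geo.circle_ring(ctr, r),))
            for i, ctr in enumerate(centers)
        ]
    if n == 3:
        r = 150.0
        centers = [(c - 80.0, c - 55.0), (c + 80.0, c - 55.0), (c, c + 83.0)]
        return [
            SetShape(LABELS[i], (geo.circle_ring(ctr, r),))
            for i, ctr in enumerate(centers)
        ]
    if n == 4:
        params = _ELLIPSES_4
    elif n == 5:
        params = _ELLIPSES_5
    elif n == 6:
        shapes = []
        for i, (x1, y1, x2, y2, x3, y3) in enumerate(_TRIANGLES_6):
            verts = [_to_canvas(x1, y1), _to_canvas(x2, y2), _to_canvas(x3, y3)]
            shapes.append(SetShape(LABELS[i], (geo.polygon_ring(verts),)))
        return shapes
    else:
        raise ValueError(f"classic layout supports 2..6 sets, got {n}")
    shapes = []
    for i, (ecx, ecy, w, h, ang) in enumerate(params):
        center = _to_canvas(ecx, ecy)
        # unit-square rotation is counter-clockwise with y up; flipping the
        # y axis for screen coordinates mirrors it, hence the negation
        ring = geo.ellipse_ring(
            center, w / 2.0 * CANVAS, h / 2.0 * CANVAS, -ang, n_points=256
        )
        shapes.append(SetShape(LABELS[i], (ring,)))
    return shapes


def classic_layout(n: int, font_size: float = DEFAULT_FONT_SIZE) -> LayoutSpec:
    """Classical Venn template for ``n`` sets (2-6).

    Circles for 2-3 sets, the standard ellipse arrangements for 4-5, and a
    six-triangle arrangement for 6 sets.
    """
    if not 2 <= n <= 6:
        raise ValueError(f"classic layout supports 2..6 sets, got {n}")
    return compose_layout(MODE_CLASSIC, _classic_shapes(n), font_size=font_size)


# ---------------------------------------------------------------------------
# Edwards templates
# ---------------------------------------------------------------------------


def _edwards_wave(k: int, theta: np.ndarray) -> np.ndarray:
    """Smoothed square wave for the k-th set (k >= 4): +1 where the band
    runs outside the central circle, -1 inside, with ``2**(k-3)`` teeth.

    The tooth phases follow a binary-counter pattern (sign of
    ``cos(2**(k-3) * 2 * theta / 2)``): within every quadrant all sign
    combinations of the active bands occur, which is what makes every one
    of the 63 regions non-empty.
    """
    m = 2 ** (k - 3)
    return np.tanh(_ED_SQUARENESS * np.cos(m * theta)) / math.tanh(_ED_SQUARENESS)


def _edwards_band(k: int, center: tuple[float, float]) -> tuple[np.ndarray, ...]:
    theta = np.linspace(0.0, 2 * np.pi, _ED_BAND_POINTS, endpoint=False)
    radius = _ED_RADIUS * (1.0 + _ED_AMPLITUDE * _edwards_wave(k, theta))
    w = _ED_HALF_WIDTHS[k]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    outer = np.column_stack(
        [center[0] + (radius + w) * cos_t, center[1] + (radius + w) * sin_t]
    )
    inner = np.column_stack(
        [center[0] + (radius - w) * cos_t, center[1] + (radius - w) * sin_t]
    )
    return (geo.close_ring(outer), geo.close_ring(inner))


def _edwards_shapes(n: int) -> list[SetShape]:
    c = CANVAS / 2.0
    m = _ED_MARGIN
    frame = (m, m, CANVAS - m, CANVAS - m)
    shapes = [
        SetShape("A", (geo.rect_ring(frame[0], frame[1], c, frame[3]),)),  # left
    ]
    if n >= 2:
        shapes.append(
            SetShape("B", (geo.rect_ring(frame[0], frame[1], frame[2], c),))  # top
        )
    if n >= 3:
        shapes.append(SetShape("C", (geo.circle_ring((c, c), _ED_RADIUS, 512),)))
    for k in range(4, n + 1):
        shapes.append(SetShape(LABELS[k - 1], _edwards_band(k, (c, c))))
    return shapes


def edwards_layout(n: int, font_size: float = DEFAULT_FONT_SIZE) -> LayoutSpec:
    """Edwards-Venn template for ``n`` sets (2-6).

    Set A is the left half of the chart frame, B the top half, C a central
    circle; sets 4-6 are closed serpentine bands whose centre radius
    oscillates in and out of the circle with ``2**(k-3)`` teeth, so band k
    crosses the circle boundary exactly ``2 * 2**(k-3)`` times.
    """
    if not 2 <= n <= 6:
        raise ValueError(f"edwards layout supports 2..6 sets, got {n}")
    return compose_layout(MODE_EDWARDS, _edwards_shapes(n), font_size=font_size)


def build_layout(mode: str, n: int, font_size: float = DEFAULT_FONT_SIZE) -> LayoutSpec:
    if mode == MODE_CLASSIC:
        return classic_layout(n, font_size)
    if mode == MODE_EDWARDS:
        return edwards_layout(n, font_size)
    raise ValueError(f"unknown layout mode {mode!r}")
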