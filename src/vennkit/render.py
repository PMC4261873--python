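"""SVG rendering of Venn diagrams and companion bar charts, plus PNG export.

Diagrams are emitted as deterministic SVG 1.1: one translucent evenodd
path per set, a count label at every region anchor (or at an external
callout when the region is too small), and list names outside their
shapes.  Counts that do not fit their region's character budget are shown
as ``?`` on screen, with the full value always preserved in a ``<title>``
element so it remains machine-readable.

PNG export rasterizes the SVG subset this module emits (paths, lines,
text) with Pillow.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree
from PIL import Image, ImageChops, ImageDraw, ImageFont

from .errors import DocumentError, VennKitError
from .io_formats import VennSeries
from .layout import Callout, LayoutSpec, plan_callouts
from .setcore import (
    MODE_VALUE_SUM,
    RegionTable,
    list_size_stats,
    region_sort_key,
    shared_distribution,
)

# Okabe-Ito colorblind-safe palette
DEFAULT_PALETTE = (
    "#0072B2",
    "#E69F00",
    "#009E73",
    "#CC79A7",
    "#56B4E9",
    "#D55E00",
)


@dataclass(frozen=True)
class RenderOptions:
    """Rendering knobs; defaults give a readable six-set diagram."""

    palette: tuple[str, ...] = DEFAULT_PALETTE
    fill_opacity: float = 0.4
    font_size: float = 13.0
    include_stats: bool = False
    output_format: str = "svg"  # svg | png
    png_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_opacity <= 1.0:
            raise VennKitError("fill opacity must lie in [0, 1]")
        if self.output_format not in ("svg", "png"):
            raise VennKitError("output format must be svg or png")


def _num_text(value: float) -> str:
    value = float(value)
    return str(int(value)) if value.is_integer() else f"{value:g}"


def format_count(value: float, budget: int) -> str:
    """Decimal rendering of ``value`` if it fits ``budget`` characters,
    else a question mark (the full value travels as metadata)."""
    if budget < 1:
        raise VennKitError("character budget must be at least 1")
    if value < 0:
        raise VennKitError("counts are non-negative")
    text = _num_text(value)
    return text if len(text) <= budget else "?"


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _path_d(rings: Sequence[np.ndarray]) -> str:
    parts = []
    for ring in rings:
        pts = ring[:-1] if np.array_equal(ring[0], ring[-1]) else ring
        coords = " L ".join(f"{_fmt(x)} {_fmt(y)}" for x, y in pts)
        parts.append(f"M {coords} Z")
    return " ".join(parts)


def _text(
    x: float,
    y: float,
    content: str,
    size: float,
    fill: str = "#222222",
    title: str | None = None,
    anchor: str = "middle",
) -> str:
    t = f"<title>{escape(title)}</title>" if title else ""
    return (
        f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}" '
        f'font-family="sans-serif" text-anchor="{anchor}" fill="{fill}">'
        f"{t}{escape(content)}</text>"
    )


def render_diagram(
    layout: LayoutSpec, table: RegionTable, options: RenderOptions | None = None
) -> str:
    """Render one diagram to an SVG document string.

    Pure function of its inputs: identical arguments give byte-identical
    SVG.  Every region's full count is embedded as ``<title>`` metadata on
    its label, even when the visible text is ``?`` or lives on a callout.
    """
    options = options or RenderOptions()
    if table.n_lists != layout.n:
        raise VennKitError(
            f"layout is for {layout.n} lists but the table has {table.n_lists}"
        )
    if len(options.palette) < layout.n:
        raise VennKitError(
            f"palette has {len(options.palette)} colors for {layout.n} sets"
        )
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(layout.width)}" height="{_fmt(layout.height)}" '
        f'viewBox="0 0 {_fmt(layout.width)} {_fmt(layout.height)}">',
        f'<rect width="{_fmt(layout.width)}" height="{_fmt(layout.height)}" '
        f'fill="#ffffff"/>',
    ]
    for shape, color in zip(layout.shapes, options.palette):
        parts.append(
            f'<path d="{_path_d(shape.rings)}" fill="{color}" '
            f'fill-opacity="{_fmt(options.fill_opacity)}" fill-rule="evenodd" '
            f'stroke="#444444" stroke-width="1"/>'
        )
    callouts = plan_callouts(layout, table, font_size=options.font_size)
    callout_regions = {c.region: c for c in callouts}
    for c in callouts:
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in c.line)
        parts.append(
            f'<polyline points="{pts}" fill="none" stroke="#888888" '
            f'stroke-width="0.8"/>'
        )
    dy = options.font_size * 0.35  # visual vertical centring
    for key in sorted(layout.anchors, key=region_sort_key):
        count = table.counts.get(key)
        if count is None:
            continue
        title = f"{key}={_num_text(count)}"
        if key in callout_regions:
            x, y = callout_regions[key].label_point
            text = _num_text(count)
        else:
            x, y = layout.anchors[key]
            text = format_count(count, max(layout.budgets.get(key, 1), 1))
        parts.append(_text(x, y + dy, text, options.font_size, title=title))
    for shape, color in zip(layout.shapes, options.palette):
        nx, ny = layout.name_points[shape.label]
        name = table.names.get(shape.label, shape.label)
        parts.append(
            _text(nx, ny + dy, name, options.font_size + 1, fill=color)
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _bar_panel(
    x0: float,
    y0: float,
    width: float,
    height: float,
    values: Sequence[float],
    labels: Sequence[str],
    title: str,
    color: str,
    font: float,
) -> list[str]:
    parts = [_text(x0 + width / 2, y0 + font, title, font + 1)]
    top = y0 + 2.2 * font
    floor = y0 + height - 1.8 * font
    span = floor - top
    vmax = max(max(values), 1)
    slot = width / max(len(values), 1)
    bar_w = slot * 0.6
    for i, (val, lab) in enumerate(zip(values, labels)):
        h = span * val / vmax
        bx = x0 + i * slot + (slot - bar_w) / 2
        by = floor - h
        parts.append(
            f'<rect x="{_fmt(bx)}" y="{_fmt(by)}" width="{_fmt(bar_w)}" '
            f'height="{_fmt(h)}" fill="{color}" fill-opacity="0.8"/>'
        )
        parts.append(_text(bx + bar_w / 2, by - 3, _num_text(val), font))
        parts.append(_text(bx + bar_w / 2, floor + 1.2 * font, lab, font))
    return parts


def render_stats_charts(
    series: Sequence[VennSeries],
    table: RegionTable,
    options: RenderOptions | None = None,
) -> str:
    """Companion statistics: list sizes, and the number of elements
    specific to one list or shared by k lists, as two SVG bar charts."""
    options = options or RenderOptions()
    if table.mode == MODE_VALUE_SUM:
        raise VennKitError("statistics charts need element counts, not value sums")
    sizes = list_size_stats(series)
    dist = shared_distribution(table)
    width, height = 700.0, 260.0
    font = options.font_size
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        f'<rect width="{_fmt(width)}" height="{_fmt(height)}" fill="#ffffff"/>',
    ]
    parts += _bar_panel(
        20, 10, width / 2 - 40, height - 20,
        [float(s) for s in sizes],
        [s.name for s in series],
        "List sizes",
        DEFAULT_PALETTE[0],
        font,
    )
    ks = sorted(dist)
    parts += _bar_panel(
        width / 2 + 20, 10, width / 2 - 40, height - 20,
        [dist[k] for k in ks],
        [str(k) for k in ks],
        "Elements shared by k lists",
        DEFAULT_PALETTE[2],
        font,
    )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# rasterization of vennkit's own SVG output
# ---------------------------------------------------------------------------


def _parse_color(color: str, opacity: float) -> tuple[int, int, int, int]:
    color = color.lstrip("#")
    r, g, b = (int(color[i : i + 2], 16) for i in (0, 2, 4))
    return (r, g, b, int(round(255 * opacity)))


def _path_rings(d: str) -> list[list[tuple[float, float]]]:
    tokens = d.replace(",", " ").split()
    rings: list[list[tuple[float, float]]] = []
    current: list[tuple[float, float]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in ("M", "L"):
            current.append((float(tokens[i + 1]), float(tokens[i + 2])))
            i += 3
        elif tok == "Z":
            if current:
                rings.append(current)
            current = []
            i += 1
        else:  # implicit lineto coordinates
            current.append((float(tok), float(tokens[i + 1])))
            i += 2
    if current:
        rings.append(current)
    return rings


def _evenodd_mask(
    size: tuple[int, int], rings: list[list[tuple[float, float]]], scale: float
) -> Image.Image:
    mask = Image.new("L", size, 0)
    for ring in rings:
        ring_img = Image.new("L", size, 0)
        ImageDraw.Draw(ring_img).polygon(
            [(x * scale, y * scale) for x, y in ring], fill=255
        )
        mask = ImageChops.difference(mask, ring_img)  # xor on {0, 255}
    return mask


def rasterize(svg_text: str, scale: float = 1.0) -> bytes:
    """Rasterize a vennkit SVG document to PNG bytes.

    Handles the element subset vennkit emits: evenodd-filled paths,
    rectangles, polylines and anchored text.  Output dimensions are the
    SVG canvas times ``scale``.
    """
    try:
        root = etree.fromstring(svg_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"invalid SVG document: {exc}") from exc
    if etree.QName(root).localname != "svg":
        raise DocumentError("not an SVG document")
    width = float(root.get("width", 0))
    height = float(root.get("height", 0))
    if width <= 0 or height <= 0:
        raise DocumentError("SVG document lacks positive width/height")
    size = (int(round(width * scale)), int(round(height * scale)))
    img = Image.new("RGBA", size, (255, 255, 255, 255))
    for el in root.iter():
        tag = etree.QName(el).localname
        if tag == "rect":
            x = float(el.get("x", 0)) * scale
            y = float(el.get("y", 0)) * scale
            w = float(el.get("width", 0)) * scale
            h = float(el.get("height", 0)) * scale
            fill = el.get("fill", "none")
            if fill != "none":
                opacity = float(el.get("fill-opacity", 1.0))
                layer = Image.new("RGBA", size, (0, 0, 0, 0))
                ImageDraw.Draw(layer).rectangle(
                    [x, y, x + w, y + h], fill=_parse_color(fill, opacity)
                )
                img = Image.alpha_composite(img, layer)
        elif tag == "path":
            rings = _path_rings(el.get("d", ""))
            fill = el.get("fill", "none")
            layer = Image.new("RGBA", size, (0, 0, 0, 0))
            if fill != "none" and rings:
                opacity = float(el.get("fill-opacity", 1.0))
                mask = _evenodd_mask(size, rings, scale)
                color_img = Image.new("RGBA", size, _parse_color(fill, opacity))
                layer.paste(color_img, (0, 0), mask)
            stroke = el.get("stroke", "none")
            if stroke != "none":
                draw = ImageDraw.Draw(layer)
                sw = max(1, int(round(float(el.get("stroke-width", 1)) * scale)))
                for ring in rings:
                    pts = [(x * scale, y * scale) for x, y in ring]
                    draw.line(pts + pts[:1], fill=_parse_color(stroke, 1.0), width=sw)
            img = Image.alpha_composite(img, layer)
        elif tag == "polyline":
            pts = [
                (float(p.split(",")[0]) * scale, float(p.split(",")[1]) * scale)
                for p in el.get("points", "").split()
            ]
            if len(pts) >= 2:
                layer = Image.new("RGBA", size, (0, 0, 0, 0))
                stroke = el.get("stroke", "#000000")
                sw = max(1, int(round(float(el.get("stroke-width", 1)) * scale)))
                ImageDraw.Draw(layer).line(pts, fill=_parse_color(stroke, 1.0), width=sw)
                img = Image.alpha_composite(img, layer)
        elif tag == "text":
            # <title> children are metadata, not visible text
            visible = el.text or ""
            for child in el:
                if child.tail:
                    visible += child.tail
            if not visible:
                continue
            x = float(el.get("x", 0)) * scale
            y = float(el.get("y", 0)) * scale
            fsize = int(round(float(el.get("font-size", 12)) * scale))
            try:
                font = ImageFont.load_default(size=max(fsize, 1))
            except TypeError:  # older Pillow
                font = ImageFont.load_default()
            layer = Image.new("RGBA", size, (0, 0, 0, 0))
            draw = ImageDraw.Draw(layer)
            bbox = draw.textbbox((0, 0), visible, font=font)
            tw, th = bbox[2] - bbox[0], bbox[3] - bbox[1]
            anchor = el.get("text-anchor", "start")
            tx = x - tw / 2 if anchor == "middle" else x
            draw.text(
                (tx, y - th),
                visible,
                font=font,
                fill=_parse_color(el.get("fill", "#000000"), 1.0),
            )
            img = Image.alpha_composite(img, layer)
    buf = io.BytesIO()
    img.convert("RGB").save(buf, format="PNG")
    return buf.getvalue()
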