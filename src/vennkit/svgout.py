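"""Render a laid-out diagram plus region counts to standalone SVG 1.1.

Output is a self-contained UTF-8 document with a viewBox and no external
resources.  Each set curve becomes one semi-transparent filled element so
overlaps stay visible; each region's exclusive count becomes a text element
anchored inside its region, carrying the stable id ``region-<label>`` and
an embedded ``<title>`` tooltip naming the set combination (the scripted
analog of hovering over a number in a GUI).  Rendering is deterministic:
identical inputs give byte-identical documents.
"""

from __future__ import annotations

import math
import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from collections.abc import Sequence

from .errors import InputError
from .geometry import Circle, Ellipse, HalfPlaneRect, SerpentineBand, Shape
from .layouts import CENTER, DiagramSpec, Placement
from .setcore import RegionPartition, combo_name, region_counts

logger = logging.getLogger("vennkit")

#: Paul Tol's muted qualitative scheme - 8 colourblind-safe fills.
DEFAULT_PALETTE = (
    "#332288", "#88CCEE", "#44AA99", "#117733",
    "#999933", "#DDCC77", "#CC6677", "#AA4499",
)


@dataclass(frozen=True)
class StyleConfig:
    palette: tuple[str, ...] = DEFAULT_PALETTE
    fill_opacity: float = 0.4
    stroke_color: str = "#333333"
    stroke_width: float = 1.5
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 16.0
    show_zero_counts: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fill_opacity <= 1.0:
            raise InputError("fill_opacity must be in (0, 1]")
        if not self.palette:
            raise InputError("palette must not be empty")

    def fill(self, index: int, n: int) -> str:
        if len(self.palette) < n and index == 0:
            logger.warning(
                "palette has %d colours for %d sets; cycling",
                len(self.palette), n,
            )
        return self.palette[index % len(self.palette)]


def _f(value: float) -> str:
    """Fixed, locale-free number formatting for coordinates."""
    return f"{value:.2f}".rstrip("0").rstrip(".")


def _shape_element(shape: Shape) -> ET.Element:
    if isinstance(shape, Circle):
        return ET.Element(
            "circle", cx=_f(shape.cx), cy=_f(shape.cy), r=_f(shape.r)
        )
    if isinstance(shape, Ellipse):
        el = ET.Element(
            "ellipse", cx=_f(shape.cx), cy=_f(shape.cy),
            rx=_f(shape.rx), ry=_f(shape.ry),
        )
        if shape.angle:
            el.set(
                "transform",
                f"rotate({_f(shape.angle)} {_f(shape.cx)} {_f(shape.cy)})",
            )
        return el
    if isinstance(shape, HalfPlaneRect):
        mx = 0.5 * (shape.x0 + shape.x1)
        my = 0.5 * (shape.y0 + shape.y1)
        if shape.side == "left":
            box = (shape.x0, shape.y0, mx, shape.y1)
        elif shape.side == "right":
            box = (mx, shape.y0, shape.x1, shape.y1)
        elif shape.side == "top":
            box = (shape.x0, shape.y0, shape.x1, my)
        else:
            box = (shape.x0, my, shape.x1, shape.y1)
        return ET.Element(
            "rect", x=_f(box[0]), y=_f(box[1]),
            width=_f(box[2] - box[0]), height=_f(box[3] - box[1]),
        )
    if isinstance(shape, SerpentineBand):
        return ET.Element("path", d=_serpentine_path(shape))
    raise InputError(f"cannot render shape {shape!r}")


def _serpentine_path(band: SerpentineBand, arc_samples: int = 16) -> str:
    """Closed path: square-wave outer boundary forward, inner circle back.

    Vertices are inserted exactly at tooth transitions so the teeth render
    crisply; each arc is approximated by short line segments.
    """
    half = math.pi / band.lobes

    def pt(radius: float, theta: float) -> str:
        return (
            f"{_f(band.cx + radius * math.cos(theta))},"
            f"{_f(band.cy + radius * math.sin(theta))}"
        )

    cmds: list[str] = []
    for k in range(2 * band.lobes):
        t0 = band.phase + k * half
        radius = band.r_out if k % 2 == 0 else band.r_in
        for j in range(arc_samples + 1):
            theta = t0 + half * j / arc_samples
            prefix = "M" if not cmds else "L"
            cmds.append(f"{prefix}{pt(radius, theta)}")
    # inner boundary, reverse direction
    total = 2 * band.lobes * arc_samples
    for j in range(total + 1):
        theta = band.phase + 2 * math.pi * (1 - j / total)
        cmds.append(f"L{pt(band.r_in, theta)}")
    return " ".join(cmds) + " Z"


def _set_label_positions(spec: DiagramSpec) -> list[tuple[str, float, float]]:
    """Place each set's name just outside its curve."""
    out: list[tuple[str, float, float]] = []

    def outward(name: str, cx: float, cy: float, extent: float) -> None:
        dx, dy = cx - CENTER[0], cy - CENTER[1]
        norm = math.hypot(dx, dy)
        if norm < 1e-9:
            dx, dy, norm = 0.0, -1.0, 1.0
        out.append(
            (name, cx + dx / norm * (extent + 18), cy + dy / norm * (extent + 18))
        )

    def label_shapes(names: Sequence[str], shapes: Sequence[Shape]) -> None:
        for name, shape in zip(names, shapes):
            if isinstance(shape, Circle):
                outward(name, shape.cx, shape.cy, shape.r)
            elif isinstance(shape, Ellipse):
                outward(name, shape.cx, shape.cy, max(shape.rx, shape.ry))
            elif isinstance(shape, HalfPlaneRect):
                if shape.side == "left":
                    out.append((name, shape.x0 + 10, shape.y0 - 8))
                elif shape.side == "right":
                    out.append((name, shape.x1 - 10, shape.y0 - 8))
                elif shape.side == "top":
                    out.append((name, shape.x1 + 8, shape.y0 + 14))
                else:
                    out.append((name, shape.x1 + 8, shape.y1 - 4))
            elif isinstance(shape, SerpentineBand):
                theta = shape.phase + math.pi / (2 * shape.lobes)
                out.append(
                    (
                        name,
                        shape.cx + (shape.r_out + 14) * math.cos(theta),
                        shape.cy + (shape.r_out + 14) * math.sin(theta),
                    )
                )

    if spec.nested is None:
        label_shapes(spec.set_names, spec.shapes)
    else:
        comp = spec.nested
        label_shapes(comp.outer_names, comp.outer_shapes)
        ext = comp.placements[0]
        for i, name in enumerate(comp.inner_names):
            out.append(
                (
                    name,
                    ext.center[0],
                    ext.center[1] + ext.disc_radius + 16 + 14 * i,
                )
            )
    return out


def render_svg(
    spec: DiagramSpec,
    part: RegionPartition,
    style: StyleConfig | None = None,
) -> str:
    """Render diagram + counts to an SVG document string."""
    style = style or StyleConfig()
    if spec.n != part.n:
        raise InputError(
            f"diagram has {spec.n} sets but partition has {part.n}"
        )
    if spec.set_names != part.set_names:
        raise InputError("diagram and partition set names disagree")

    w, h = spec.canvas
    root = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        version="1.1",
        width=_f(w),
        height=_f(h),
        viewBox=f"0 0 {_f(w)} {_f(h)}",
    )

    shapes_group = ET.SubElement(root, "g", id="sets")

    def add_shape(parent: ET.Element, shape: Shape, index: int) -> None:
        el = _shape_element(shape)
        el.set("fill", style.fill(index, spec.n))
        el.set("fill-opacity", _f(style.fill_opacity))
        el.set("stroke", style.stroke_color)
        el.set("stroke-width", _f(style.stroke_width))
        parent.append(el)

    if spec.nested is None:
        for i, shape in enumerate(spec.shapes):
            add_shape(shapes_group, shape, i)
    else:
        comp = spec.nested
        for i, shape in enumerate(comp.outer_shapes):
            add_shape(shapes_group, shape, i)
        for host in sorted(comp.placements):
            placement = comp.placements[host]
            ET.SubElement(
                shapes_group, "circle",
                cx=_f(placement.center[0]), cy=_f(placement.center[1]),
                r=_f(placement.disc_radius),
                fill="none", stroke="#bbbbbb",
                attrib={"stroke-width": "0.5"},
            )
            tx = placement.center[0] - placement.scale * CENTER[0]
            ty = placement.center[1] - placement.scale * CENTER[1]
            g = ET.SubElement(
                shapes_group, "g",
                transform=(
                    f"translate({_f(tx)} {_f(ty)}) scale({_f(placement.scale)})"
                ),
            )
            for j, shape in enumerate(comp.inner_shapes):
                add_shape(g, shape, len(comp.outer_names) + j)

    labels_group = ET.SubElement(
        root, "g", id="set-labels",
        attrib={
            "font-family": style.font_family,
            "font-size": _f(style.font_size),
            "text-anchor": "middle",
            "font-weight": "bold",
        },
    )
    for name, x, y in _set_label_positions(spec):
        text = ET.SubElement(labels_group, "text", x=_f(x), y=_f(y))
        text.text = name

    counts_group = ET.SubElement(
        root, "g", id="counts",
        attrib={
            "font-family": style.font_family,
            "font-size": _f(style.font_size * (0.75 if spec.n >= 7 else 1.0)),
            "text-anchor": "middle",
        },
    )
    counts = region_counts(part, include_empty=True)
    for label in sorted(spec.region_anchors):
        count = counts[label]
        if count == 0 and not style.show_zero_counts:
            continue
        x, y = spec.region_anchors[label]
        text = ET.SubElement(
            counts_group, "text", id=f"region-{label}", x=_f(x), y=_f(y)
        )
        title = ET.SubElement(text, "title")
        title.text = f"{combo_name(label, part.set_names)}: {count}"
        title.tail = str(count)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def write_svg(
    spec: DiagramSpec,
    part: RegionPartition,
    path: str | os.PathLike[str],
    style: StyleConfig | None = None,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(render_svg(spec, part, style))
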