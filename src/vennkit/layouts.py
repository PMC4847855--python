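"""Diagram layout builders: Classic (1–5 sets), Edwards (2–6), Nested (5–8).

Each builder assigns one closed shape (or, for the nested family, one
composed placement) per set on a fixed 800x800 canvas and computes an
anchor point for every one of the ``2**n - 1`` subset regions via grid
sampling (:mod:`vennkit.geometry`).  Layouts are fully deterministic.

Classic uses circles up to three sets, Venn's four-ellipse construction for
four, and the rotationally symmetric five-ellipse construction (congruent
ellipses rotated in 72-degree steps) for five.

Edwards uses a left half-frame, a bottom half-frame, a central circle, and
serpentine (cogwheel) bands with 2, 4 and 8 teeth for sets four to six.
Tooth transitions are phase-shifted so that within every quadrant the
on/off states of the bands run through a full binary counter, which is what
realises all ``2**n`` membership combinations.

Nested composes two Classic diagrams: the first four sets form an outer
diagram, and a miniature Classic diagram of the remaining sets is inlaid
into every outer region (plus one standalone copy outside the outer
curves, hosting the combinations that touch no outer set).  Outer sets own
the low bits of the full region label, inner sets the high bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .errors import CapabilityError, InputError
from .geometry import (
    DEFAULT_RESOLUTION,
    Circle,
    Ellipse,
    GridSample,
    HalfPlaneRect,
    SerpentineBand,
    Shape,
    point_membership,
)

CANVAS = 800.0
CENTER = (CANVAS / 2.0, CANVAS / 2.0)

#: Miniature discs keep this fraction of the host region's clearance so the
#: whole inlaid diagram stays strictly inside the host region.
MINIATURE_FILL = 0.8

#: Cap on the standalone (exterior) miniature's disc radius.
EXTERIOR_RADIUS_CAP = 150.0

# Venn's four-ellipse construction and the symmetric five-ellipse family,
# given as (cx, cy, rx, ry, angle) fractions of the canvas (y up, angles
# counter-clockwise); converted to SVG y-down coordinates at build time.
_VENN4 = (
    (0.350, 0.400, 0.36, 0.225, 140.0),
    (0.450, 0.500, 0.36, 0.225, 140.0),
    (0.544, 0.500, 0.36, 0.225, 40.0),
    (0.644, 0.400, 0.36, 0.225, 40.0),
)
_VENN5 = (
    (0.428, 0.449, 0.435, 0.250, 155.0),
    (0.469, 0.543, 0.435, 0.250, 83.0),
    (0.558, 0.523, 0.435, 0.250, 11.0),
    (0.578, 0.432, 0.435, 0.250, 119.0),
    (0.489, 0.383, 0.435, 0.250, 47.0),
)

# Edwards constants: central circle radius and band half-thicknesses.
_EDWARDS_FRAME = (60.0, 60.0, 740.0, 740.0)
_EDWARDS_R = 190.0
_EDWARDS_BANDS = (  # (inner depth, outer reach, lobes)
    (80.0, 80.0, 2),
    (50.0, 50.0, 4),
    (25.0, 25.0, 8),
)


@dataclass(frozen=True)
class Placement:
    """Where one miniature inner diagram sits: centre, uniform scale about
    the inner diagram's canvas centre, and the radius of the disc it is
    guaranteed to stay inside."""

    center: tuple[float, float]
    scale: float
    disc_radius: float

    def transform(self, point: tuple[float, float]) -> tuple[float, float]:
        return (
            self.center[0] + self.scale * (point[0] - CENTER[0]),
            self.center[1] + self.scale * (point[1] - CENTER[1]),
        )

    def inverse(self, point: tuple[float, float]) -> tuple[float, float]:
        return (
            CENTER[0] + (point[0] - self.center[0]) / self.scale,
            CENTER[1] + (point[1] - self.center[1]) / self.scale,
        )


@dataclass(frozen=True)
class NestedComposition:
    """Outer classic diagram plus inlaid miniature inner diagrams.

    ``placements`` maps each outer region label — and 0 for the exterior
    standalone copy — to that region's miniature placement.
    """

    outer_names: tuple[str, ...]
    inner_names: tuple[str, ...]
    outer_shapes: tuple[Shape, ...]
    inner_shapes: tuple[Shape, ...]
    inner_anchors: dict[int, tuple[float, float]]
    placements: dict[int, Placement]


@dataclass(frozen=True)
class DiagramSpec:
    """A fully laid-out diagram: shapes, per-region anchors, canvas.

    ``shapes`` holds one shape per set for classic/edwards layouts and the
    outer shapes for nested layouts (the composition carries the rest).
    ``region_anchors`` has exactly ``2**n - 1`` keys, and every anchor's
    membership bitmask equals its label.
    """

    layout_kind: str
    set_names: tuple[str, ...]
    shapes: tuple[Shape, ...]
    region_anchors: dict[int, tuple[float, float]]
    canvas: tuple[float, float] = (CANVAS, CANVAS)
    nested: NestedComposition | None = None

    @property
    def n(self) -> int:
        return len(self.set_names)

    def membership(self, point: tuple[float, float]) -> int:
        """Full region label of an arbitrary canvas point."""
        if self.nested is None:
            return point_membership(point, self.shapes)
        comp = self.nested
        outer = point_membership(point, comp.outer_shapes)
        inner = 0
        for host, placement in comp.placements.items():
            d = math.hypot(
                point[0] - placement.center[0], point[1] - placement.center[1]
            )
            if d <= placement.disc_radius:
                inner = point_membership(placement.inverse(point), comp.inner_shapes)
                break
        return outer | (inner << len(comp.outer_names))


def _check_names(set_names: Sequence[str]) -> tuple[str, ...]:
    names = tuple(set_names)
    if len(set(names)) != len(names):
        raise InputError("set names must be unique")
    if any(not n for n in names):
        raise InputError("set names must be non-empty")
    return names


def classic_shapes(n: int) -> tuple[Shape, ...]:
    """Shape list of the classic layout for 1–5 sets on the 800x800 canvas."""
    if n == 1:
        return (Circle(400.0, 400.0, 250.0),)
    if n == 2:
        return (Circle(310.0, 400.0, 210.0), Circle(490.0, 400.0, 210.0))
    if n == 3:
        shapes = []
        for k in range(3):
            ang = math.radians(270.0 + 120.0 * k)
            shapes.append(
                Circle(
                    400.0 + 105.0 * math.cos(ang),
                    415.0 + 105.0 * math.sin(ang),
                    185.0,
                )
            )
        return tuple(shapes)
    if n == 4:
        params = _VENN4
    elif n == 5:
        params = _VENN5
    else:
        raise CapabilityError(
            "classic layout supports 1-5 sets; use the nested layout for more"
        )
    return tuple(
        Ellipse(
            CANVAS * cx,
            CANVAS * (1.0 - cy),  # flip to SVG y-down
            CANVAS * rx,
            CANVAS * ry,
            -angle,  # y-flip reverses rotation sense
        )
        for cx, cy, rx, ry, angle in params
    )


def edwards_shapes(n: int) -> tuple[Shape, ...]:
    """Shape list of the Edwards layout for 2–6 sets."""
    if not 2 <= n <= 6:
        raise CapabilityError("edwards layout supports 2-6 sets")
    x0, y0, x1, y1 = _EDWARDS_FRAME
    shapes: list[Shape] = [
        HalfPlaneRect(x0, y0, x1, y1, "left"),
        HalfPlaneRect(x0, y0, x1, y1, "bottom"),
    ]
    if n >= 3:
        shapes.append(Circle(CENTER[0], CENTER[1], _EDWARDS_R))
    for depth, reach, lobes in _EDWARDS_BANDS[: max(0, n - 3)]:
        shapes.append(
            SerpentineBand(
                CENTER[0],
                CENTER[1],
                _EDWARDS_R - depth,
                _EDWARDS_R + reach,
                lobes,
                phase=-math.pi / (2 * lobes),
            )
        )
    return tuple(shapes)


def _anchors_from_grid(
    shapes: Sequence[Shape], n: int, resolution: int
) -> dict[int, tuple[float, float]]:
    grid = GridSample(shapes, (0.0, 0.0, CANVAS, CANVAS), resolution)
    anchors: dict[int, tuple[float, float]] = {}
    for label in range(1, 1 << n):
        pts = grid.hits(label)
        if pts.shape[0] == 0:
            raise InputError(
                f"layout geometry failed to realise region {label} of {n} sets"
            )
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        if point_membership(centroid, shapes) == label:
            anchors[label] = centroid
        else:
            anchors[label], _ = grid.pole(label)
    return anchors


def build_classic(
    set_names: Sequence[str],
    canvas: tuple[float, float] = (CANVAS, CANVAS),
    resolution: int = DEFAULT_RESOLUTION,
) -> DiagramSpec:
    """Classic layout for 1–5 sets: circles up to three sets, then the
    four- and five-ellipse constructions."""
    names = _check_names(set_names)
    shapes = classic_shapes(len(names))
    anchors = _anchors_from_grid(shapes, len(names), resolution)
    return DiagramSpec("classic", names, shapes, anchors, canvas)


def build_edwards(
    set_names: Sequence[str],
    canvas: tuple[float, float] = (CANVAS, CANVAS),
    resolution: int = DEFAULT_RESOLUTION,
) -> DiagramSpec:
    """Edwards layout for 2–6 sets: half-frames, circle, cogwheel bands."""
    names = _check_names(set_names)
    shapes = edwards_shapes(len(names))
    anchors = _anchors_from_grid(shapes, len(names), resolution)
    return DiagramSpec("edwards", names, shapes, anchors, canvas)


def _bounding_radius(shapes: Sequence[Shape]) -> float:
    """Conservative radius about the canvas centre enclosing all shapes."""
    radius = 0.0
    for shape in shapes:
        if isinstance(shape, Circle):
            d = math.hypot(shape.cx - CENTER[0], shape.cy - CENTER[1])
            radius = max(radius, d + shape.r)
        elif isinstance(shape, Ellipse):
            d = math.hypot(shape.cx - CENTER[0], shape.cy - CENTER[1])
            radius = max(radius, d + max(shape.rx, shape.ry))
        else:  # pragma: no cover - nested miniatures are classic-only
            raise InputError("nested miniatures support circles/ellipses only")
    return radius


def build_nested(
    set_names: Sequence[str],
    canvas: tuple[float, float] = (CANVAS, CANVAS),
    resolution: int = DEFAULT_RESOLUTION,
) -> DiagramSpec:
    """Nested layout for 5–8 sets.

    The first four sets form the outer classic diagram; the remaining
    ``n - 4`` sets form the inner group, drawn as a miniature classic
    diagram inside every outer region and once more outside all outer
    curves.  The anchor of full label ``(outer bits o, inner bits m)`` is
    the inner-region-``m`` anchor of the miniature hosted by outer region
    ``o`` when ``m > 0`` (``o = 0`` meaning the exterior copy), and a point
    of region ``o`` outside its miniature when ``m = 0``.
    """
    names = _check_names(set_names)
    n = len(names)
    if not 5 <= n <= 8:
        raise CapabilityError("nested layout supports 5-8 sets")
    n_outer = 4
    outer_names, inner_names = names[:n_outer], names[n_outer:]
    n_inner = n - n_outer

    outer_shapes = classic_shapes(n_outer)
    inner_shapes = classic_shapes(n_inner)
    inner_anchors = _anchors_from_grid(inner_shapes, n_inner, resolution)
    inner_radius = _bounding_radius(inner_shapes)

    grid = GridSample(outer_shapes, (0.0, 0.0, CANVAS, CANVAS), resolution)

    placements: dict[int, Placement] = {}
    for host in range(0, 1 << n_outer):
        center, clearance = grid.pole(host)
        disc = MINIATURE_FILL * clearance
        if host == 0:
            disc = min(disc, EXTERIOR_RADIUS_CAP)
        placements[host] = Placement(center, disc / inner_radius, disc)

    anchors: dict[int, tuple[float, float]] = {}
    for host in range(0, 1 << n_outer):
        placement = placements[host]
        for m in range(1, 1 << n_inner):
            anchors[host | (m << n_outer)] = placement.transform(inner_anchors[m])
        if host > 0:
            anchors[host] = _host_only_anchor(grid, host, placement)

    comp = NestedComposition(
        outer_names=outer_names,
        inner_names=inner_names,
        outer_shapes=outer_shapes,
        inner_shapes=inner_shapes,
        inner_anchors=inner_anchors,
        placements=placements,
    )
    spec = DiagramSpec("nested", names, outer_shapes, anchors, canvas, comp)
    _verify_anchors(spec)
    return spec


def _host_only_anchor(
    grid: GridSample, host: int, placement: Placement
) -> tuple[float, float]:
    """A point inside outer region ``host`` but outside its miniature disc.

    Among the region's grid hits clear of the disc (with a one-cell margin)
    the deepest-in-region one is chosen, so the count for "host sets only"
    sits inside its region yet off the inlaid diagram.
    """
    pts = grid.hits(host)
    d = np.hypot(pts[:, 0] - placement.center[0], pts[:, 1] - placement.center[1])
    clear = pts[d > placement.disc_radius + grid.cell]
    if clear.shape[0] == 0:
        raise InputError(
            f"outer region {host} leaves no room beside its miniature"
        )
    # favour depth inside the host region: recompute local depth cheaply as
    # distance to the nearest hit of any *other* label among a subsample
    # would be costly; the farthest-from-disc point is a robust stand-in.
    idx = int(np.argmax(np.hypot(
        clear[:, 0] - placement.center[0], clear[:, 1] - placement.center[1]
    )))
    # walk back toward the disc centre until safely interior (away from the
    # thin tips regions can have at their far ends)
    far = clear[idx]
    dd = np.hypot(clear[:, 0] - far[0], clear[:, 1] - far[1])
    order = np.argsort(dd)
    pick = clear[order[min(len(order) - 1, len(order) // 8)]]
    return (float(pick[0]), float(pick[1]))


def _verify_anchors(spec: DiagramSpec) -> None:
    bad = [
        label
        for label, anchor in spec.region_anchors.items()
        if spec.membership(anchor) != label
    ]
    if bad:
        raise InputError(
            f"anchor membership check failed for labels {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )


def build_layout(
    layout: str,
    set_names: Sequence[str],
    resolution: int = DEFAULT_RESOLUTION,
) -> DiagramSpec:
    """Dispatch on layout name; ``auto`` picks classic for up to four sets
    and nested for five to eight."""
    n = len(set_names)
    if layout == "auto":
        layout = "classic" if n <= 4 else "nested"
    if layout == "classic":
        return build_classic(set_names, resolution=resolution)
    if layout == "edwards":
        return build_edwards(set_names, resolution=resolution)
    if layout == "nested":
        return build_nested(set_names, resolution=resolution)
    raise InputError(f"unknown layout {layout!r}")
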