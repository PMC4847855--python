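"""Shape membership predicates and grid-sampled region statistics.

The layout builders place one closed shape per set and need, for every one
of the ``2**n - 1`` subset regions, a point that is provably inside that
region (the anchor where the count is printed) plus a rough area estimate.
Both come from classifying a regular grid of sample points with the shape
membership predicates below.  Anchors default to the centroid of a region's
grid hits; when the centroid of a non-convex region falls outside it, the
fallback is the region's deepest sample point (the argmax of the Euclidean
distance transform over the region mask — a grid approximation of the pole
of inaccessibility), which is guaranteed to satisfy the membership test.

All membership predicates are total, deterministic and treat boundaries as
inside (closed curves, ``<=`` comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import InputError

#: Default number of grid samples per axis.
DEFAULT_RESOLUTION = 400


# ---------------------------------------------------------------------------
# shapes

@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise InputError("circle radius must be positive")

    def contains(self, x, y):
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2


@dataclass(frozen=True)
class Ellipse:
    """Axis lengths are semi-axes; ``angle`` rotates the major axis,
    in degrees, positive clockwise in SVG (y-down) coordinates."""

    cx: float
    cy: float
    rx: float
    ry: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.rx <= 0 or self.ry <= 0:
            raise InputError("ellipse semi-axes must be positive")

    def contains(self, x, y):
        a = math.radians(self.angle)
        ca, sa = math.cos(a), math.sin(a)
        dx = x - self.cx
        dy = y - self.cy
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        return (u / self.rx) ** 2 + (v / self.ry) ** 2 <= 1.0


@dataclass(frozen=True)
class HalfPlaneRect:
    """One half of an axis-aligned rectangle, split through its middle.

    ``side`` names the kept half in SVG coordinates: ``left``/``right``
    split at the vertical midline, ``top``/``bottom`` at the horizontal one
    (``bottom`` is larger *y*).
    """

    x0: float
    y0: float
    x1: float
    y1: float
    side: str

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise InputError("rectangle must have positive extent")
        if self.side not in ("left", "right", "top", "bottom"):
            raise InputError(f"unknown side {self.side!r}")

    def contains(self, x, y):
        inside = (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)
        mx = 0.5 * (self.x0 + self.x1)
        my = 0.5 * (self.y0 + self.y1)
        if self.side == "left":
            return inside & (x <= mx)
        if self.side == "right":
            return inside & (x >= mx)
        if self.side == "top":
            return inside & (y <= my)
        return inside & (y >= my)


@dataclass(frozen=True)
class SerpentineBand:
    """A lobed annulus approximating the cogwheel curves of Edwards-style
    diagrams for the fourth and later sets.

    A point is inside when its polar radius about the band centre lies
    between ``r_in`` and ``r_out(theta)``, where the outer boundary is a
    phase-shifted square wave alternating between ``r_out`` (tooth) and
    ``r_in`` (gap) over ``lobes`` angular periods.  With doubling lobe
    counts and phases offset by half a tooth per doubling, the teeth of
    successive bands enumerate every on/off combination within each
    quadrant of the host diagram.
    """

    cx: float
    cy: float
    r_in: float
    r_out: float
    lobes: int
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.r_in < self.r_out):
            raise InputError("need 0 < r_in < r_out")
        if self.lobes < 1 or (self.lobes & (self.lobes - 1)) != 0:
            raise InputError("lobe count must be a positive power of two")

    def _tooth(self, theta):
        half_period = math.pi / self.lobes
        k = np.floor((theta - self.phase) / half_period).astype(np.int64)
        return (k % 2) == 0

    def contains(self, x, y):
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        r_limit = np.where(self._tooth(theta), self.r_out, self.r_in)
        result = (r >= self.r_in) & (r <= r_limit)
        if np.isscalar(x) and np.isscalar(y):
            return bool(result)
        return result


Shape = Circle | Ellipse | HalfPlaneRect | SerpentineBand


def serpentine_membership(point: tuple[float, float], band: SerpentineBand) -> bool:
    """Convenience scalar predicate for serpentine bands."""
    return bool(band.contains(point[0], point[1]))


# ---------------------------------------------------------------------------
# grid sampling

def point_membership(point: tuple[float, float], shapes: Sequence[Shape]) -> int:
    """Bitmask of the shapes containing ``point`` (bit ``i-1`` for shape
    ``i``); boundaries count as inside."""
    if not shapes:
        raise InputError("shape list must be non-empty")
    x, y = float(point[0]), float(point[1])
    label = 0
    for i, shape in enumerate(shapes):
        if shape.contains(x, y):
            label |= 1 << i
    return label


@dataclass(frozen=True)
class RegionGeometry:
    """Grid statistics for one region: where to write its count and how big
    it is, in canvas units squared."""

    label: int
    anchor: tuple[float, float]
    est_area: float
    sample_count: int


class GridSample:
    """Grid classification of a rectangle against an ordered shape list.

    Holds the per-cell label array plus helpers (hit coordinates, deepest
    point) used by both :func:`estimate_regions` and the nested layout
    builder, which needs masks of individual regions to size the inlaid
    miniature diagrams.
    """

    def __init__(
        self,
        shapes: Sequence[Shape],
        bounds: tuple[float, float, float, float],
        resolution: int = DEFAULT_RESOLUTION,
    ) -> None:
        if resolution < 64:
            raise InputError("grid resolution must be at least 64")
        x0, y0, x1, y1 = bounds
        if x1 <= x0 or y1 <= y0:
            raise InputError("bounds rectangle must have positive extent")
        if not shapes:
            raise InputError("shape list must be non-empty")
        self.shapes = tuple(shapes)
        self.bounds = (x0, y0, x1, y1)
        self.resolution = resolution
        self.dx = (x1 - x0) / resolution
        self.dy = (y1 - y0) / resolution
        self.cell_area = self.dx * self.dy
        #: radius of a bounding circle of one grid cell
        self.cell = max(self.dx, self.dy)
        xs = x0 + (np.arange(resolution) + 0.5) * self.dx
        ys = y0 + (np.arange(resolution) + 0.5) * self.dy
        self.xv, self.yv = np.meshgrid(xs, ys)  # [row=y, col=x]
        labels = np.zeros(self.xv.shape, dtype=np.int64)
        for i, shape in enumerate(self.shapes):
            labels |= shape.contains(self.xv, self.yv).astype(np.int64) << i
        self.labels = labels

    def hit_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def hits(self, label: int) -> np.ndarray:
        """(k, 2) array of sample-point coordinates with this label."""
        mask = self.labels == label
        return np.column_stack([self.xv[mask], self.yv[mask]])

    def pole(self, label: int) -> tuple[tuple[float, float], float]:
        """Deepest sample point of a region and its clearance.

        Clearance is the distance-transform value scaled to canvas units:
        a lower bound (up to one cell) on the distance from the returned
        point to anything outside the region.
        """
        mask = self.labels == label
        if not mask.any():
            raise InputError(f"no grid hits for label {label}")
        depth = distance_transform_edt(mask, sampling=(self.dy, self.dx))
        row, col = np.unravel_index(int(np.argmax(depth)), depth.shape)
        point = (float(self.xv[row, col]), float(self.yv[row, col]))
        return point, float(depth[row, col])


def estimate_regions(
    shapes: Sequence[Shape],
    bounds: tuple[float, float, float, float],
    resolution: int = DEFAULT_RESOLUTION,
) -> list[RegionGeometry]:
    """Classify a sample grid and summarise every non-empty region.

    Regions with zero grid hits are absent from the result.  Anchors are
    centroid-with-fallback as described in the module docstring and always
    satisfy ``point_membership(anchor, shapes) == label``.
    """
    grid = GridSample(shapes, bounds, resolution)
    out: list[RegionGeometry] = []
    for label, count in sorted(grid.hit_counts().items()):
        if label == 0:
            continue
        pts = grid.hits(label)
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        anchor = centroid
        if point_membership(centroid, shapes) != label:
            anchor, _ = grid.pole(label)
        out.append(
            RegionGeometry(
                label=label,
                anchor=anchor,
                est_area=count * grid.cell_area,
                sample_count=count,
            )
        )
    return out
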