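"""Planar polygon primitives: areas, bounding boxes, the edge-crossing
position test, and the exact clipping refiner.

Two polygon representations coexist. :class:`PolygonF` holds the original
floating-point ring (a segmentation boundary, a map feature); :class:`PolygonI`
holds its integer-grid image after multiplication by a scaling factor ``k``
(see :mod:`pixelcross.scaling`). The pixel refiner decides pixel membership
with the even-odd crossing-number test implemented here; the exact refiner
delegates polygon clipping to shapely/GEOS.

All coordinates are planar Cartesian; no CRS handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Union

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InvalidPolygonError


class MBB(NamedTuple):
    """Axis-aligned minimum bounding box (closed intervals)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def intersects(self, other: "MBB") -> bool:
        """Closed-interval overlap test: touching boxes count as intersecting."""
        return (
            self.xmin <= other.xmax
            and other.xmin <= self.xmax
            and self.ymin <= other.ymax
            and other.ymin <= self.ymax
        )

    def intersection(self, other: "MBB") -> "MBB | None":
        xmin = max(self.xmin, other.xmin)
        ymin = max(self.ymin, other.ymin)
        xmax = min(self.xmax, other.xmax)
        ymax = min(self.ymax, other.ymax)
        if xmin > xmax or ymin > ymax:
            return None
        return MBB(xmin, ymin, xmax, ymax)

    def union(self, other: "MBB") -> "MBB":
        return MBB(
            min(self.xmin, other.xmin),
            min(self.ymin, other.ymin),
            max(self.xmax, other.xmax),
            max(self.ymax, other.ymax),
        )


@dataclass(frozen=True)
class PolygonF:
    """Simple polygon ring with floating-point vertices.

    The ring is implicitly closed: the last stored vertex connects back to the
    first, and no duplicated closing vertex is stored. Simplicity (no
    self-intersection) and nonzero area are enforced by :meth:`validate`,
    which every ingest path calls.
    """

    vertices: tuple[tuple[float, float], ...]
    id: object = None

    def __post_init__(self):
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    def validate(self) -> "PolygonF":
        if len(self.vertices) < 3:
            raise InvalidPolygonError(
                f"polygon {self.id!r}: needs >= 3 vertices, got {len(self.vertices)}"
            )
        for x, y in self.vertices:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvalidPolygonError(f"polygon {self.id!r}: non-finite vertex")
        sh = _ShapelyPolygon(self.vertices)
        if not sh.is_valid or not sh.is_simple:
            raise InvalidPolygonError(f"polygon {self.id!r}: ring is not simple")
        if sh.area == 0.0:
            raise InvalidPolygonError(f"polygon {self.id!r}: zero area")
        return self

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class PolygonI:
    """Integer-grid polygon ring derived from a :class:`PolygonF` by
    coordinate-wise multiplication by ``k`` and rounding."""

    vertices: tuple[tuple[int, int], ...]
    k: int = 1
    source_id: object = None

    def __post_init__(self):
        object.__setattr__(
            self, "vertices", tuple((int(x), int(y)) for x, y in self.vertices)
        )
        if len(self.vertices) < 3:
            raise InvalidPolygonError(
                f"integer polygon from {self.source_id!r}: fewer than 3 vertices"
            )


AnyPolygon = Union[PolygonF, PolygonI]


def polygon_area(p: PolygonF) -> float:
    """Unsigned shoelace area of the ring, in coordinate-units squared.

    Orientation-independent. Uses Neumaier-compensated summation so long
    rings with large coordinates do not lose the small cross terms.

    Raises
    ------
    InvalidPolygonError
        If the ring is degenerate (zero area).
    """
    verts = p.vertices
    n = len(verts)
    if n < 3:
        raise InvalidPolygonError("polygon needs >= 3 vertices")
    total = 0.0
    comp = 0.0
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        term = x1 * y2 - x2 * y1
        s = total + term
        if abs(total) >= abs(term):
            comp += (total - s) + term
        else:
            comp += (term - s) + total
        total = s
    area = abs(total + comp) / 2.0
    if area == 0.0:
        raise InvalidPolygonError(f"polygon {p.id!r}: degenerate ring (zero area)")
    return area


def extract_mbb(p: AnyPolygon) -> MBB:
    """Coordinate-wise min/max bounding box of the ring's vertices."""
    xs = [v[0] for v in p.vertices]
    ys = [v[1] for v in p.vertices]
    return MBB(min(xs), min(ys), max(xs), max(ys))


def point_in_polygon(p: PolygonI, x: float, y: float) -> bool:
    """Even-odd crossing-number position test against an integer polygon.

    Casts a horizontal ray towards +x and counts crossings with the ring's
    non-horizontal edges. An edge with endpoints ``(x1, y1)``, ``(x2, y2)``
    is crossed when ``y`` lies in the edge's half-open y-span (lower endpoint
    inclusive, upper exclusive — so a ray through a shared vertex is counted
    exactly once) and

        ``x <= x1 + (y - y1) * (x2 - x1) / (y2 - y1)``

    i.e. the point lies on or left of the edge at height ``y``. Horizontal
    edges are never counted. The point is inside iff the count is odd.

    With half-integer pixel centers against integer vertices the on-edge
    equality case is measure-zero but still resolved deterministically
    (on-edge counts as a crossing).
    """
    verts = p.vertices
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 <= y < y2) or (y2 <= y < y1):
            if x <= x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                inside = not inside
    return inside


def points_in_polygon_grid(
    p: PolygonI, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Vectorized even-odd test over a Cartesian grid of query points.

    Evaluates exactly the predicate of :func:`point_in_polygon` (same
    expression, same half-open convention, same IEEE-754 arithmetic) for all
    points ``(xs[j], ys[i])`` as data-parallel array operations — the
    portable analogue of a per-pixel GPU kernel.

    Parameters
    ----------
    xs, ys : 1-D float arrays of query x- and y-coordinates.

    Returns
    -------
    Boolean array of shape ``(len(ys), len(xs))``; entry ``[i, j]`` is the
    membership of point ``(xs[j], ys[i])``.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    crossings = np.zeros((ys.size, xs.size), dtype=np.int64)
    verts = p.vertices
    n = len(verts)
    xcol = xs[np.newaxis, :]
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        span = (
            ((y1 <= ys) & (ys < y2)) if y2 > y1 else ((y2 <= ys) & (ys < y1))
        )
        if not span.any():
            continue
        xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        crossings += (span[:, np.newaxis] & (xcol <= xint[:, np.newaxis]))
    return (crossings & 1).astype(bool)


def segment_intersects_box(
    a: tuple[float, float], b: tuple[float, float], box: MBB
) -> bool:
    """True iff the closed segment ``ab`` meets the closed box.

    Liang–Barsky slab clipping; a segment touching only a box corner or edge
    counts as intersecting.
    """
    x0, y0 = a
    x1, y1 = b
    dx = x1 - x0
    dy = y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - box.xmin),
        (dx, box.xmax - x0),
        (-dy, y0 - box.ymin),
        (dy, box.ymax - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return False  # parallel and outside the slab
        else:
            t = q / p
            if p < 0.0:
                if t > t1:
                    return False
                if t > t0:
                    t0 = t
            else:
                if t < t0:
                    return False
                if t < t1:
                    t1 = t
    return t0 <= t1


def exact_intersection_area(a: PolygonF, b: PolygonF) -> tuple[float, float]:
    """Exact intersection and union areas via polygon clipping (GEOS).

    Returns ``(inter, union)`` with ``union = area(a) + area(b) - inter``.
    This is the CPU geometry refiner and the correctness oracle for the
    pixel refiner.
    """
    sa = a.to_shapely()
    sb = b.to_shapely()
    for poly, src in ((sa, a), (sb, b)):
        if not poly.is_valid:
            raise InvalidPolygonError(f"polygon {src.id!r}: not a valid simple ring")
    inter = sa.intersection(sb).area
    union = sa.area + sb.area - inter
    return inter, union
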