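"""Adaptive float-to-integer scaling of polygon pairs.

Pixelization needs integer vertices on a shared grid. Each candidate pair is
scaled by a factor ``K`` drawn from a small ascending candidate set (default
``[50, 100, 150]``): coordinates are multiplied by ``K`` and rounded, the
polygon's area is re-measured as the count of unit pixels whose centers fall
inside the scaled ring, and the relative conversion error

    ``error = |pixel_count / K**2 - area_original| / area_original``

is required to stay within a threshold (default 5%) for *both* polygons of
the pair. The smallest qualifying ``K`` wins — fewer pixels means less work
downstream. Pairs that no candidate qualifies are routed to a configurable
fallback (default: the exact geometry refiner).

``K`` is selected per pair, not per polygon: a shared factor keeps both
polygons on the same pixel grid, which the intersection count requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np

from .errors import ConfigError, DegenerateScalingError, InvalidPolygonError
from .geometry import (
    MBB,
    PolygonF,
    PolygonI,
    extract_mbb,
    points_in_polygon_grid,
    polygon_area,
)


class Fallback(str, Enum):
    """What to do with a pair that exceeds the error threshold at every K."""

    EXACT_REFINER = "exact_refiner"
    ACCEPT_LARGEST_K = "accept_largest_k"
    REJECT = "reject"


@dataclass(frozen=True)
class ScalingConfig:
    k_candidates: tuple[int, ...] = (50, 100, 150)
    error_threshold: float = 0.05
    fallback: Fallback = Fallback.EXACT_REFINER

    def __post_init__(self):
        object.__setattr__(self, "k_candidates", tuple(int(k) for k in self.k_candidates))
        object.__setattr__(self, "fallback", Fallback(self.fallback))
        ks = self.k_candidates
        if not ks:
            raise ConfigError("k_candidates must be non-empty")
        if any(k <= 0 for k in ks) or any(a >= b for a, b in zip(ks, ks[1:])):
            raise ConfigError(f"k_candidates must be strictly ascending positives: {ks}")
        if not (0.0 < self.error_threshold < 1.0):
            raise ConfigError(f"error_threshold must be in (0, 1): {self.error_threshold}")


@dataclass(frozen=True)
class ScaledPair:
    """A candidate pair after integer scaling at a shared factor ``k``.

    Carries everything the pixel refiner needs: the integer polygons, their
    scaled MBBs (floor/ceil-rounded, so they contain the scaled float boxes),
    the per-polygon in-ring pixel counts, the original shoelace areas, and
    the per-polygon conversion errors.
    """

    k: int
    poly_a: PolygonI
    poly_b: PolygonI
    mbb_a: MBB
    mbb_b: MBB
    mbb_pair: MBB
    pixel_count_a: int
    pixel_count_b: int
    error_a: float
    error_b: float
    area_a: float
    area_b: float


@dataclass(frozen=True)
class FallbackDecision:
    """Verdict for a pair that no candidate factor qualified."""

    action: Fallback
    poly_a: PolygonF
    poly_b: PolygonF
    best: ScaledPair | None = None  # largest-K attempt, when one scaled cleanly


def scale_mbb(box: MBB, k: int) -> MBB:
    """Scale a float box to the integer grid: lower bounds floored, upper
    bounds ceiled, so the result contains the scaled float box."""
    return MBB(
        math.floor(box.xmin * k),
        math.floor(box.ymin * k),
        math.ceil(box.xmax * k),
        math.ceil(box.ymax * k),
    )


def _round_half_away(v: float) -> int:
    # round-half-away-from-zero; python's round() is banker's rounding
    return math.floor(v + 0.5) if v >= 0.0 else math.ceil(v - 0.5)


def scale_polygon(p: PolygonF, k: int) -> PolygonI:
    """Map each vertex to ``(round(k*x), round(k*y))`` (ties away from zero),
    collapsing consecutive duplicates produced by rounding.

    Raises
    ------
    DegenerateScalingError
        If the rounded ring has < 3 distinct vertices or zero area; callers
        treat this as "unqualified at this k", not as a hard failure.
    """
    scaled = [(_round_half_away(x * k), _round_half_away(y * k)) for x, y in p.vertices]
    dedup: list[tuple[int, int]] = []
    for v in scaled:
        if not dedup or v != dedup[-1]:
            dedup.append(v)
    if len(dedup) > 1 and dedup[0] == dedup[-1]:
        dedup.pop()
    if len(dedup) < 3:
        raise DegenerateScalingError(
            f"polygon {p.id!r} collapses to {len(dedup)} vertices at k={k}"
        )
    # signed shoelace on integers — exact
    area2 = 0
    n = len(dedup)
    for i in range(n):
        x1, y1 = dedup[i]
        x2, y2 = dedup[(i + 1) % n]
        area2 += x1 * y2 - x2 * y1
    if area2 == 0:
        raise DegenerateScalingError(f"polygon {p.id!r} has zero area at k={k}")
    return PolygonI(tuple(dedup), k=k, source_id=p.id)


def pixel_centers(box: MBB) -> tuple[np.ndarray, np.ndarray]:
    """Half-integer center coordinates of the unit pixels tiling an integer
    box: pixel ``(i, j)`` covers ``[i, i+1) x [j, j+1)`` with center
    ``(i + 0.5, j + 0.5)``. Returns ``(xs, ys)``; either may be empty."""
    xs = np.arange(int(box.xmin), int(box.xmax), dtype=np.int64) + 0.5
    ys = np.arange(int(box.ymin), int(box.ymax), dtype=np.int64) + 0.5
    return xs, ys


def pixel_area(p: PolygonI, domain: MBB | None = None) -> int:
    """Number of unit pixels whose center lies inside the scaled ring.

    This count is Eq-of-conversion's ``area_scaling``: with unit pixels it
    *is* the polygon's area on the integer grid. The enumeration domain
    defaults to the polygon's own bounding box; any containing domain gives
    the same count, since centers outside the box are outside the ring.
    """
    box = domain if domain is not None else extract_mbb(p)
    xs, ys = pixel_centers(box)
    if xs.size == 0 or ys.size == 0:
        return 0
    return int(points_in_polygon_grid(p, xs, ys).sum())


def conversion_error(pixel_count: int, k: int, area_original: float) -> float:
    """Relative area distortion of pixelization at factor ``k``:
    ``|pixel_count / k**2 - area_original| / area_original``."""
    if area_original <= 0.0:
        raise InvalidPolygonError(f"area_original must be > 0, got {area_original}")
    return abs(pixel_count / (k * k) - area_original) / area_original


def _scale_pair_at(a: PolygonF, b: PolygonF, k: int) -> ScaledPair:
    area_a = polygon_area(a)
    area_b = polygon_area(b)
    pa = scale_polygon(a, k)
    pb = scale_polygon(b, k)
    mbb_a = scale_mbb(extract_mbb(a), k)
    mbb_b = scale_mbb(extract_mbb(b), k)
    cnt_a = pixel_area(pa, mbb_a)
    cnt_b = pixel_area(pb, mbb_b)
    return ScaledPair(
        k=k,
        poly_a=pa,
        poly_b=pb,
        mbb_a=mbb_a,
        mbb_b=mbb_b,
        mbb_pair=mbb_a.union(mbb_b),
        pixel_count_a=cnt_a,
        pixel_count_b=cnt_b,
        error_a=conversion_error(cnt_a, k, area_a),
        error_b=conversion_error(cnt_b, k, area_b),
        area_a=area_a,
        area_b=area_b,
    )


def select_scaling_factor(
    a: PolygonF, b: PolygonF, cfg: ScalingConfig = ScalingConfig()
) -> Union[ScaledPair, FallbackDecision]:
    """Pick the smallest candidate ``K`` at which both polygons scale without
    degeneracy and both conversion errors stay within the threshold.

    Candidates are tried in ascending order; a degenerate rounding at some
    ``k`` merely skips that candidate. If none qualifies, returns the
    configured :class:`FallbackDecision` (carrying the largest-K attempt so
    ``accept_largest_k`` can still use it).
    """
    last_attempt: ScaledPair | None = None
    for k in cfg.k_candidates:
        try:
            sp = _scale_pair_at(a, b, k)
        except DegenerateScalingError:
            continue
        last_attempt = sp
        if max(sp.error_a, sp.error_b) <= cfg.error_threshold:
            return sp
    return FallbackDecision(action=cfg.fallback, poly_a=a, poly_b=b, best=last_attempt)
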