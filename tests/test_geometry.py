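"""Polygon primitives: areas, bounding boxes, crossing test, exact clipping."""

import math

import numpy as np
import pytest

from pixelcross import (
    MBB,
    InvalidPolygonError,
    PolygonF,
    PolygonI,
    exact_intersection_area,
    extract_mbb,
    point_in_polygon,
    polygon_area,
    segment_intersects_box,
)
from pixelcross.geometry import points_in_polygon_grid

from conftest import winding_number_inside


@pytest.mark.parametrize(
    "verts, expected",
    [
        ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
        ([(0, 0), (1, 0), (0, 1)], 0.5),
        ([(0, 1), (1, 1), (1, 0), (0, 0)], 1.0),  # reversed orientation
    ],
)
def test_polygon_area(verts, expected):
    assert polygon_area(PolygonF(verts)) == pytest.approx(expected)


def test_degenerate_ring_rejected():
    with pytest.raises(InvalidPolygonError):
        polygon_area(PolygonF([(0, 0), (1, 1), (2, 2)]))
    with pytest.raises(InvalidPolygonError):
        PolygonF([(0, 0), (2, 2), (2, 0), (0, 2)]).validate()  # bowtie


@pytest.mark.parametrize(
    "verts, expected",
    [
        ([(0, 0), (1, 0), (0, 1)], MBB(0, 0, 1, 1)),
        ([(-2, -1), (-1, -1), (-1, -3)], MBB(-2, -3, -1, -1)),
        ([(0, 0), (10, 0), (10, 10), (0, 10)], MBB(0, 0, 10, 10)),
    ],
)
def test_extract_mbb(verts, expected):
    mbb = extract_mbb(PolygonF(verts))
    assert mbb == expected
    assert all(mbb.xmin <= x <= mbb.xmax and mbb.ymin <= y <= mbb.ymax for x, y in verts)


def test_point_in_polygon_examples(l_shape):
    square = PolygonI([(0, 0), (10, 0), (10, 10), (0, 10)], k=1)
    assert point_in_polygon(square, 5.5, 5.5)
    assert not point_in_polygon(square, 15.5, 5.5)
    # concave notch of the L: the missing quadrant
    assert not point_in_polygon(l_shape, 3.5, 3.5)
    assert point_in_polygon(l_shape, 1.5, 3.5)
    assert point_in_polygon(l_shape, 3.5, 1.5)


def test_crossing_test_agrees_with_winding_oracle():
    """Even-odd crossing test vs an independent winding-number oracle on
    10^4 random star-shaped polygons and query points off edges."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 10_000:
        n = int(rng.integers(3, 12))
        ang = 2 * np.pi * (np.arange(n) + rng.uniform(0.05, 0.95, n)) / n
        rad = rng.uniform(5, 40, n)
        verts = [
            (int(round(r * math.cos(a))), int(round(r * math.sin(a))))
            for r, a in zip(rad, ang)
        ]
        dedup = [v for i, v in enumerate(verts) if v != verts[i - 1]]
        if len(dedup) < 3:
            continue
        poly = PolygonI(dedup, k=1)
        from shapely.geometry import Polygon as SP

        sp = SP(dedup)
        if not sp.is_valid:
            continue
        pts = rng.uniform(-45, 45, size=(4, 2))
        for x, y in pts:
            x, y = float(x) + 0.5, float(y) + 0.5
            from shapely.geometry import Point

            if sp.exterior.distance(Point(x, y)) < 1e-6:
                continue  # skip the measure-zero on-edge band
            assert point_in_polygon(poly, x, y) == winding_number_inside(dedup, x, y)
            checked += 1


def test_grid_test_matches_scalar_test():
    """Vectorized grid evaluation is bit-identical to the scalar test."""
    rng = np.random.default_rng(3)
    poly = PolygonI([(0, 0), (7, 2), (9, 9), (4, 12), (-2, 6)], k=1)
    xs = np.arange(-3, 11) + 0.5
    ys = np.arange(-2, 13) + 0.5
    grid = points_in_polygon_grid(poly, xs, ys)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            assert grid[i, j] == point_in_polygon(poly, float(x), float(y))


@pytest.mark.parametrize(
    "a, b, box, expected",
    [
        ((0, 0), (10, 10), MBB(4, 4, 6, 6), True),
        ((0, 0), (1, 0), MBB(5, 5, 6, 6), False),
        ((0, 2), (2, 0), MBB(0, 0, 1, 1), True),  # touches only the corner
        ((0.5, 0.5), (0.6, 0.6), MBB(0, 0, 1, 1), True),  # fully inside
        ((0, 5), (10, 5), MBB(2, 5, 4, 9), True),  # grazes the bottom edge
    ],
)
def test_segment_intersects_box(a, b, box, expected):
    assert segment_intersects_box(a, b, box) is expected


def test_segment_box_brute_force_sampling():
    """Parametric fine sampling of the segment as the independent oracle."""
    rng = np.random.default_rng(7)
    t = np.linspace(0.0, 1.0, 2001)
    for _ in range(300):
        a = rng.uniform(-5, 5, 2)
        b = rng.uniform(-5, 5, 2)
        sx = np.sort(rng.uniform(-5, 5, 2))
        sy = np.sort(rng.uniform(-5, 5, 2))
        box = MBB(sx[0], sy[0], sx[1], sy[1])
        pts_x = a[0] + t * (b[0] - a[0])
        pts_y = a[1] + t * (b[1] - a[1])
        tol = 1e-9
        hit = bool(
            np.any(
                (pts_x >= box.xmin - tol) & (pts_x <= box.xmax + tol)
                & (pts_y >= box.ymin - tol) & (pts_y <= box.ymax + tol)
            )
        )
        # dense sampling finds a hit -> the slab test must agree; a slab-test
        # hit the sampling missed can only be a sub-resolution graze
        if hit:
            assert segment_intersects_box(tuple(a), tuple(b), box)


def test_exact_intersection_examples(unit_square, offset_square, triangle):
    inter, union = exact_intersection_area(unit_square, offset_square)
    assert inter == pytest.approx(0.25)
    assert union == pytest.approx(1.75)
    inter, union = exact_intersection_area(triangle, triangle)
    assert inter == pytest.approx(union) == pytest.approx(0.5)
    far = PolygonF([(5, 5), (6, 5), (6, 6), (5, 6)], id="far")
    inter, union = exact_intersection_area(unit_square, far)
    assert inter == 0.0
    assert union == pytest.approx(2.0)


def test_exact_intersection_symmetry_and_self(paired_datasets):
    ds_a, ds_b = paired_datasets
    for a, b in list(zip(ds_a, ds_b))[:10]:
        i1, u1 = exact_intersection_area(a, b)
        i2, u2 = exact_intersection_area(b, a)
        assert i1 == pytest.approx(i2) and u1 == pytest.approx(u2)
        assert 0 <= i1 <= min(polygon_area(a), polygon_area(b)) + 1e-12
        assert u1 >= max(polygon_area(a), polygon_area(b)) - 1e-12
        self_i, _ = exact_intersection_area(a, a)
        assert self_i == pytest.approx(polygon_area(a))
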