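"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point, Polygon as ShapelyPolygon

from pixelcross import (
    FixtureSpec,
    PolygonF,
    PolygonI,
    ScaledPair,
    ScalingConfig,
    gen_pair_dataset,
    select_scaling_factor,
)


# ---------------------------------------------------------------- oracles


def winding_number_inside(vertices, x, y) -> bool:
    """Independent point-in-polygon oracle: signed-angle winding number.

    Sums the turn angles from the query point to consecutive vertices; a
    total of ~±2π means inside, ~0 outside. Valid away from edges.
    """
    v = np.asarray(vertices, dtype=float)
    dx = v[:, 0] - x
    dy = v[:, 1] - y
    ang = np.arctan2(dy, dx)
    turns = np.diff(np.concatenate([ang, ang[:1]]))
    turns = (turns + np.pi) % (2 * np.pi) - np.pi
    return abs(turns.sum()) > np.pi


def covers_pixel_count(poly: PolygonI, box) -> int:
    """Boundary-inclusive pixel-count oracle via shapely: centers covered by
    the ring (interior or boundary) — matches the `<=` on-edge convention."""
    sp = ShapelyPolygon(poly.vertices)
    count = 0
    for j in range(int(box.ymin), int(box.ymax)):
        for i in range(int(box.xmin), int(box.xmax)):
            if sp.covers(Point(i + 0.5, j + 0.5)):
                count += 1
    return count


def brute_force_mbb_pairs(objs1, objs2):
    """All-pairs closed-interval MBB intersection (filter-stage oracle)."""
    out = set()
    for o1 in objs1:
        for o2 in objs2:
            a, b = o1.mbb, o2.mbb
            if a.xmin <= b.xmax and b.xmin <= a.xmax and a.ymin <= b.ymax and b.ymin <= a.ymax:
                out.add((o1.id, o2.id))
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def unit_square() -> PolygonF:
    return PolygonF([(0, 0), (1, 0), (1, 1), (0, 1)], id="sq").validate()


@pytest.fixture(scope="session")
def offset_square() -> PolygonF:
    return PolygonF([(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)], id="sq2").validate()


@pytest.fixture(scope="session")
def triangle() -> PolygonF:
    return PolygonF([(0, 0), (1, 0), (0, 1)], id="tri").validate()


@pytest.fixture(scope="session")
def l_shape() -> PolygonI:
    return PolygonI([(0, 0), (4, 0), (4, 2), (2, 2), (2, 4), (0, 4)], k=1, source_id="L")


@pytest.fixture(scope="session")
def paired_datasets():
    """Two matched 40-polygon datasets emulating repeated segmentation runs."""
    spec = FixtureSpec(n_polygons=40, seed=11)
    return gen_pair_dataset(spec)


@pytest.fixture(scope="session")
def scaled_pairs(paired_datasets):
    """Qualified scaled pairs from the matched datasets (adaptive K)."""
    ds_a, ds_b = paired_datasets
    cfg = ScalingConfig()
    out = []
    for a, b in zip(ds_a, ds_b):
        sp = select_scaling_factor(a, b, cfg)
        if isinstance(sp, ScaledPair):
            out.append(sp)
    assert len(out) >= 30  # the fixture conditions should qualify most pairs
    return out
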