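"""Fixed-grid tiling and the MBB filter stage.

The plane is divided into equal half-open tiles ``[x0, x0+w) x [y0, y0+h)``.
Each polygon is assigned to every tile its bounding box intersects
(replication), so co-located tiles from the two datasets can be filtered
independently. Filtering builds a bulk-loaded R-tree (shapely's STRtree)
over one tile's boxes and queries it with the other's; surviving pairs —
closed-interval box intersection, touching counts — are the refinement
work units.

Replication means a pair can surface in several tiles; the canonical-tile
rule (the tile containing the lower-left corner of the two boxes' overlap)
picks exactly one owner, so each pair is refined once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import shapely
from shapely import STRtree

from .errors import ConfigError, InvalidPolygonError
from .geometry import MBB, PolygonF, extract_mbb

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Fixed-grid geometry: tile dimensions and the grid origin (lower-left)."""

    tile_width: float
    tile_height: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.tile_width <= 0 or self.tile_height <= 0:
            raise ConfigError(
                f"tile dimensions must be positive: {self.tile_width} x {self.tile_height}"
            )

    def tile_extent(self, row: int, col: int) -> MBB:
        ox, oy = self.origin
        return MBB(
            ox + col * self.tile_width,
            oy + row * self.tile_height,
            ox + (col + 1) * self.tile_width,
            oy + (row + 1) * self.tile_height,
        )

    def tile_of_point(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the half-open tile containing the point."""
        ox, oy = self.origin
        col = math.floor((x - ox) / self.tile_width)
        row = math.floor((y - oy) / self.tile_height)
        # guard against float slop at tile boundaries: the tile interval is
        # half-open, so membership is decided against the exact bounds
        while x < ox + col * self.tile_width:
            col -= 1
        while x >= ox + (col + 1) * self.tile_width:
            col += 1
        while y < oy + row * self.tile_height:
            row -= 1
        while y >= oy + (row + 1) * self.tile_height:
            row += 1
        return row, col


def default_grid(extent: MBB, divisions: int = 8) -> GridSpec:
    """Grid covering ``extent`` with ``divisions`` tiles per axis, origin at
    the extent's lower-left corner."""
    w = (extent.xmax - extent.xmin) / divisions or 1.0
    h = (extent.ymax - extent.ymin) / divisions or 1.0
    return GridSpec(tile_width=w, tile_height=h, origin=(extent.xmin, extent.ymin))


@dataclass(frozen=True)
class TileObject:
    id: object
    mbb: MBB
    v_count: int
    coords: tuple[tuple[float, float], ...]

    @property
    def polygon(self) -> PolygonF:
        return PolygonF(self.coords, id=self.id)


@dataclass
class TileConfig:
    """A tile's prepared payload: per-object id, bounding box, vertex count
    and coordinate list, plus the tile's grid extent."""

    tile_id: tuple[int, int]
    extent: MBB
    objects: list[TileObject] = field(default_factory=list)
    skipped: int = 0  # invalid polygons dropped during prepare


@dataclass(frozen=True)
class CandidatePair:
    """A pair surviving the MBB filter; the refinement work unit."""

    id_a: object
    id_b: object
    tile_id: tuple[int, int]
    mbb_a: MBB
    mbb_b: MBB
    v_count_a: int = 0
    v_count_b: int = 0


def prepare_tile(
    polygons: Sequence[PolygonF],
    tile_id: tuple[int, int] = (0, 0),
    extent: MBB | None = None,
) -> TileConfig:
    """Record per-object metadata (MBB, vertex count, coordinates) for a
    tile's polygons. Invalid polygons are skipped with a logged warning and
    counted; an empty input is an error (tiles are created non-empty)."""
    if not polygons:
        raise ConfigError(f"tile {tile_id}: empty tile input")
    tc = TileConfig(tile_id=tile_id, extent=extent if extent is not None else MBB(0, 0, 0, 0))
    for p in polygons:
        try:
            p.validate()
        except InvalidPolygonError as exc:
            logger.warning("tile %s: skipping invalid polygon: %s", tile_id, exc)
            tc.skipped += 1
            continue
        tc.objects.append(
            TileObject(id=p.id, mbb=extract_mbb(p), v_count=len(p.vertices), coords=p.vertices)
        )
    if extent is None and tc.objects:
        ext = tc.objects[0].mbb
        for o in tc.objects[1:]:
            ext = ext.union(o.mbb)
        tc.extent = ext
    return tc


def _tile_range(lo: float, hi: float, origin: float, size: float) -> range:
    """Indices i of half-open intervals [origin + i*size, origin + (i+1)*size)
    intersecting the closed interval [lo, hi]."""
    i_lo = math.floor((lo - origin) / size) - 1
    i_hi = math.floor((hi - origin) / size) + 1
    keep = [
        i
        for i in range(i_lo, i_hi + 1)
        if hi >= origin + i * size and lo < origin + (i + 1) * size
    ]
    return range(keep[0], keep[-1] + 1) if keep else range(0)


def partition_fixed_grid(
    dataset: Sequence[PolygonF], grid: GridSpec
) -> list[TileConfig]:
    """Assign every polygon to each tile its MBB intersects (replication);
    empty tiles are omitted. Returns tiles sorted by (row, col)."""
    if not dataset:
        raise ConfigError("cannot partition an empty dataset")
    buckets: dict[tuple[int, int], list[PolygonF]] = {}
    ox, oy = grid.origin
    for p in dataset:
        box = extract_mbb(p)
        for row in _tile_range(box.ymin, box.ymax, oy, grid.tile_height):
            for col in _tile_range(box.xmin, box.xmax, ox, grid.tile_width):
                buckets.setdefault((row, col), []).append(p)
    return [
        prepare_tile(buckets[tid], tid, grid.tile_extent(*tid))
        for tid in sorted(buckets)
    ]


def index_filter(t1: TileConfig, t2: TileConfig) -> list[CandidatePair]:
    """Filter stage for one co-located tile pair: bulk-load an R-tree over
    ``t2``'s boxes, probe it with each object of ``t1``, and emit pairs whose
    MBBs intersect (closed intervals — touching boxes are candidates).
    Output sorted by (id_a, id_b); set-equal to brute-force all-pairs."""
    if t1.tile_id != t2.tile_id:
        raise ConfigError(
            f"index_filter requires co-located tiles, got {t1.tile_id} vs {t2.tile_id}"
        )
    boxes2 = [shapely.box(o.mbb.xmin, o.mbb.ymin, o.mbb.xmax, o.mbb.ymax) for o in t2.objects]
    tree = STRtree(boxes2)
    pairs: list[CandidatePair] = []
    for o1 in t1.objects:
        probe = shapely.box(o1.mbb.xmin, o1.mbb.ymin, o1.mbb.xmax, o1.mbb.ymax)
        for j in tree.query(probe, predicate="intersects"):
            o2 = t2.objects[int(j)]
            if o1.mbb.intersects(o2.mbb):
                pairs.append(
                    CandidatePair(
                        id_a=o1.id,
                        id_b=o2.id,
                        tile_id=t1.tile_id,
                        mbb_a=o1.mbb,
                        mbb_b=o2.mbb,
                        v_count_a=o1.v_count,
                        v_count_b=o2.v_count,
                    )
                )
    pairs.sort(key=lambda c: (str(c.id_a), str(c.id_b)))
    return pairs


def canonical_tile(mbb_a: MBB, mbb_b: MBB, grid: GridSpec) -> tuple[int, int]:
    """Owning tile of a replicated pair: the tile containing the lower-left
    corner of the two boxes' overlap region."""
    px = max(mbb_a.xmin, mbb_b.xmin)
    py = max(mbb_a.ymin, mbb_b.ymin)
    return grid.tile_of_point(px, py)
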