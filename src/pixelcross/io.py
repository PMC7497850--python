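"""Readers and writers: GeoJSON / WKT polygon input, CSV / JSONL result
output, and the run configuration."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import shapely.wkt
import yaml

from . import __version__
from .errors import (
    ConfigError,
    FormatError,
    InvalidPolygonError,
    UnsupportedGeometryError,
)
from .geometry import PolygonF
from .partition import GridSpec
from .refine import CrossMatchResult, SamplingConfig
from .scaling import ScalingConfig
from .scheduler import SchedulerConfig

_RESULT_COLUMNS = [
    "id_a", "id_b", "k", "refiner", "qualified", "inter_px", "union_px",
    "inter_area", "union_area", "jaccard", "error_a", "error_b",
]


@dataclass
class RunConfig:
    """Full run configuration; serializable to/from YAML or JSON."""

    input_a: str | None = None
    input_b: str | None = None
    format: str | None = None  # geojson | wkt-lines | None (by extension)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    grid: GridSpec | None = None
    output: str | None = None
    output_format: str = "csv"
    log_level: str = "WARNING"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "input_a": self.input_a,
            "input_b": self.input_b,
            "format": self.format,
            "scaling": {
                "k_candidates": list(self.scaling.k_candidates),
                "error_threshold": self.scaling.error_threshold,
                "fallback": self.scaling.fallback.value,
            },
            "sampling": {"box_side": self.sampling.box_side, "enabled": self.sampling.enabled},
            "scheduler": {
                "policy": self.scheduler.policy.value,
                "n_serial_workers": self.scheduler.n_serial_workers,
                "vectorized_executor": self.scheduler.vectorized_executor,
                "work_gain_coeff": self.scheduler.work_gain_coeff,
                "transfer_cost_coeff": self.scheduler.transfer_cost_coeff,
                "batch_overhead_bytes": self.scheduler.batch_overhead_bytes,
                "rng_seed": self.scheduler.rng_seed,
            },
            "grid": None
            if self.grid is None
            else {
                "tile_width": self.grid.tile_width,
                "tile_height": self.grid.tile_height,
                "origin": list(self.grid.origin),
            },
            "output": self.output,
            "output_format": self.output_format,
            "log_level": self.log_level,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "scaling" in kw and kw["scaling"] is not None:
            s = kw["scaling"]
            kw["scaling"] = ScalingConfig(
                k_candidates=tuple(s.get("k_candidates", (50, 100, 150))),
                error_threshold=s.get("error_threshold", 0.05),
                fallback=s.get("fallback", "exact_refiner"),
            )
        if "sampling" in kw and kw["sampling"] is not None:
            kw["sampling"] = SamplingConfig(**kw["sampling"])
        if "scheduler" in kw and kw["scheduler"] is not None:
            kw["scheduler"] = SchedulerConfig(**kw["scheduler"])
        if kw.get("grid"):
            g = kw["grid"]
            kw["grid"] = GridSpec(g["tile_width"], g["tile_height"], tuple(g["origin"]))
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


def _ring_from_coords(coords, locus: str) -> tuple[tuple[float, float], ...]:
    ring = [(float(x), float(y)) for x, y in coords]
    if len(ring) >= 2 and ring[0] == ring[-1]:
        ring = ring[:-1]  # drop the closing duplicate vertex
    if len(ring) < 3:
        raise FormatError(f"{locus}: ring has fewer than 3 distinct vertices")
    return tuple(ring)


def _iter_geojson(path: Path):
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if data.get("type") == "FeatureCollection":
        features = data.get("features", [])
    elif data.get("type") == "Feature":
        features = [data]
    else:
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection or Feature")
    for i, feat in enumerate(features):
        locus = f"{path} feature {i}"
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype != "Polygon":
            raise UnsupportedGeometryError(f"{locus}: unsupported geometry {gtype!r}")
        rings = geom.get("coordinates", [])
        if len(rings) != 1:
            raise UnsupportedGeometryError(
                f"{locus}: polygons with holes are not supported"
            )
        rec_id = feat.get("id", (feat.get("properties") or {}).get("id", i))
        yield rec_id, _ring_from_coords(rings[0], locus), locus


def _iter_wkt(path: Path):
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            locus = f"{path} line {lineno}"
            try:
                geom = shapely.wkt.loads(line)
            except Exception as exc:
                raise FormatError(f"{locus}: unparseable WKT ({exc})") from exc
            if geom.geom_type != "Polygon":
                raise UnsupportedGeometryError(
                    f"{locus}: unsupported geometry {geom.geom_type!r}"
                )
            if geom.interiors:
                raise UnsupportedGeometryError(
                    f"{locus}: polygons with holes are not supported"
                )
            yield lineno, _ring_from_coords(geom.exterior.coords, locus), locus


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    if path.suffix.lower() in (".geojson", ".json"):
        return "geojson"
    if path.suffix.lower() in (".wkt", ".txt", ".csv"):
        return "wkt-lines"
    raise FormatError(f"{path}: cannot infer format; pass geojson or wkt-lines")


def iter_records(path: str | Path, fmt: str | None = None):
    """Yield ``(record_id, ring, locus)`` triples without validation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    fmt = _detect_format(path, fmt)
    if fmt == "geojson":
        yield from _iter_geojson(path)
    elif fmt == "wkt-lines":
        yield from _iter_wkt(path)
    else:
        raise FormatError(f"unknown format {fmt!r} (use geojson or wkt-lines)")


def read_polygons(path: str | Path, fmt: str | None = None) -> list[PolygonF]:
    """Read and validate a polygon dataset (GeoJSON FeatureCollection of
    Polygons, or one WKT POLYGON per line). Invalid records raise with the
    record locus in the message."""
    polygons = []
    for rec_id, ring, locus in iter_records(path, fmt):
        try:
            polygons.append(PolygonF(ring, id=rec_id).validate())
        except InvalidPolygonError as exc:
            raise InvalidPolygonError(f"{locus}: {exc}") from exc
    return polygons


def validate_file(path: str | Path, fmt: str | None = None) -> list[str]:
    """Per-record diagnostics; empty list means every record is valid."""
    problems = []
    for rec_id, ring, locus in iter_records(path, fmt):
        try:
            PolygonF(ring, id=rec_id).validate()
        except InvalidPolygonError as exc:
            problems.append(f"{locus}: {exc}")
    return problems


def write_polygons_geojson(polygons: Sequence[PolygonF], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "id": p.id,
            "properties": {},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(v) for v in p.vertices] + [list(p.vertices[0])]],
            },
        }
        for p in polygons
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=None,
                   separators=(",", ":"))
        + "\n"
    )


def _fmt9(v: float | None) -> str:
    return "" if v is None else format(v, ".9g")


def _result_row(r: CrossMatchResult) -> dict:
    return {
        "id_a": r.pair_id[0],
        "id_b": r.pair_id[1],
        "k": r.k,
        "refiner": r.refiner,
        "qualified": str(bool(r.qualified)).lower(),
        "inter_px": r.inter_px,
        "union_px": r.union_px,
        "inter_area": _fmt9(r.inter_area),
        "union_area": _fmt9(r.union_area),
        "jaccard": _fmt9(r.jaccard),
        "error_a": _fmt9(r.error_a),
        "error_b": _fmt9(r.error_b),
    }


def write_results(
    results: Sequence[CrossMatchResult],
    path: str | Path,
    fmt: str = "csv",
    metadata: dict | None = None,
) -> dict:
    """Serialize results (CSV or JSONL; areas and Jaccard at 9 significant
    digits) plus a ``<path>.meta.json`` sidecar with config, seed and
    version. Returns a small summary dict."""
    path = Path(path)
    rows = [_result_row(r) for r in results]
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_RESULT_COLUMNS, lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                fh.write(json.dumps(row, separators=(",", ":")) + "\n")
    else:
        raise ConfigError(f"unknown output format {fmt!r} (use csv or jsonl)")
    meta = {"version": __version__, **(metadata or {})}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return {"n_results": len(results), "path": str(path)}


def read_results_csv(path: str | Path) -> list[dict]:
    """Parse a results CSV back into typed records (round-trip helper)."""
    out = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            out.append(
                {
                    "id_a": row["id_a"],
                    "id_b": row["id_b"],
                    "k": int(row["k"]),
                    "refiner": row["refiner"],
                    "qualified": row["qualified"] == "true",
                    "inter_px": int(row["inter_px"]),
                    "union_px": int(row["union_px"]),
                    "inter_area": float(row["inter_area"]),
                    "union_area": float(row["union_area"]),
                    "jaccard": float(row["jaccard"]),
                    "error_a": float(row["error_a"]) if row["error_a"] else None,
                    "error_b": float(row["error_b"]) if row["error_b"] else None,
                }
            )
    return out
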