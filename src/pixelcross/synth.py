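"""Seeded synthetic polygon datasets.

Stands in for real inputs (map layers, segmentation boundaries) in tests
and examples. Polygons are star-shaped rings built from jittered points on
a circle — simple by construction, no repair loops — rescaled to an exact
target area; a fraction get concave notches (vertices pulled toward the
center), which preserves simplicity because vertex angles stay strictly
increasing. "Second-run" copies emulate a repeated segmentation: each
polygon is translated and radially jittered, so expected pairwise overlap
decreases as the perturbation scale grows.

Generation is pure in (spec, seed): the same spec always yields the same
vertex lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .geometry import MBB, PolygonF

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset.

    ``area_range`` is in coordinate-units squared; ``perturbation`` is the
    displacement scale (same units as coordinates) applied to second-run
    copies. The default shapes are compact polygons of roughly unit area in
    a 16 x 16 extent — sized so the default scaling candidates {50, 100,
    150} are in their useful regime.
    """

    n_polygons: int = 100
    extent: MBB = MBB(0.0, 0.0, 16.0, 16.0)
    area_range: tuple[float, float] = (0.5, 2.0)
    vertex_range: tuple[int, int] = (8, 24)
    concavity_fraction: float = 0.3
    perturbation: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_polygons < 1:
            raise ConfigError("n_polygons must be >= 1")
        if not (0 < self.area_range[0] <= self.area_range[1]):
            raise ConfigError(f"bad area_range {self.area_range}")
        if not (3 <= self.vertex_range[0] <= self.vertex_range[1]):
            raise ConfigError(f"bad vertex_range {self.vertex_range}")
        if not (0.0 <= self.concavity_fraction <= 1.0):
            raise ConfigError("concavity_fraction must be in [0, 1]")
        if self.perturbation < 0:
            raise ConfigError("perturbation must be >= 0")


def _shoelace(xs: np.ndarray, ys: np.ndarray) -> float:
    return 0.5 * abs(float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)))


def gen_polygon(spec: FixtureSpec, index: int) -> PolygonF:
    """Generate the ``index``-th polygon of the dataset, deterministic in
    ``(spec.seed, index)``."""
    rng = np.random.default_rng([spec.seed, index])
    n = int(rng.integers(spec.vertex_range[0], spec.vertex_range[1] + 1))
    # strictly increasing jittered angles -> star-shaped, hence simple
    angles = _TWO_PI * (np.arange(n) + rng.uniform(0.08, 0.92, n)) / n
    radii = rng.uniform(0.6, 1.0, n)
    if rng.random() < spec.concavity_fraction:
        n_notch = int(rng.integers(1, max(2, n // 4)))
        notch_idx = rng.choice(n, size=n_notch, replace=False)
        radii[notch_idx] *= rng.uniform(0.25, 0.45, n_notch)
    xs = radii * np.cos(angles)
    ys = radii * np.sin(angles)
    target = float(rng.uniform(*spec.area_range))
    s = math.sqrt(target / _shoelace(xs, ys))
    xs *= s
    ys *= s
    half_w = float(np.max(np.abs(xs)))
    half_h = float(np.max(np.abs(ys)))
    ext = spec.extent
    if 2 * half_w > ext.xmax - ext.xmin or 2 * half_h > ext.ymax - ext.ymin:
        raise ConfigError(
            f"area_range {spec.area_range} incompatible with extent {tuple(ext)}"
        )
    cx = float(rng.uniform(ext.xmin + half_w, ext.xmax - half_w))
    cy = float(rng.uniform(ext.ymin + half_h, ext.ymax - half_h))
    verts = tuple(zip((xs + cx).tolist(), (ys + cy).tolist()))
    return PolygonF(verts, id=f"p{index:04d}").validate()


def gen_dataset(spec: FixtureSpec) -> list[PolygonF]:
    return [gen_polygon(spec, i) for i in range(spec.n_polygons)]


def _perturb(p: PolygonF, rng: np.random.Generator, scale: float) -> PolygonF:
    """Translate and radially jitter a star-shaped polygon about its vertex
    centroid; positive radial factors keep it simple."""
    v = np.asarray(p.vertices, dtype=float)
    c = v.mean(axis=0)
    shift = rng.normal(0.0, scale, 2)
    factors = np.clip(1.0 + rng.normal(0.0, 0.5 * scale, len(v)), 0.2, None)
    out = c + shift + (v - c) * factors[:, None]
    return PolygonF(tuple(map(tuple, out.tolist())), id=p.id).validate()


def gen_pair_dataset(spec: FixtureSpec) -> tuple[list[PolygonF], list[PolygonF]]:
    """Two matched datasets: A as generated, B a perturbed second-run copy
    of A with the same record IDs. With perturbation 0, B equals A."""
    dataset_a = gen_dataset(spec)
    if spec.perturbation == 0.0:
        return dataset_a, list(dataset_a)
    dataset_b = [
        _perturb(p, np.random.default_rng([spec.seed, i, 1]), spec.perturbation)
        for i, p in enumerate(dataset_a)
    ]
    return dataset_a, dataset_b
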