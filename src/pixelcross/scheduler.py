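"""End-to-end cross-matching query and the task scheduler.

The query is a pipeline of tasks — parse/partition, index/filter, refine —
dispatched under one of two policies: FCFS (submission order) or PQ
(priority order). Refine tasks get a priority from a linear cost model
estimating whether the data-parallel (vectorized) executor beats the serial
one: the estimated pixel work must outweigh the cost of moving the payload
to the data-parallel engine. Parse and index/filter tasks always carry the
minimum priority and never enter the vectorized executor.

Scheduling only reorders work. The per-pair results are pure functions of
the inputs, and the final result list is deduplicated and sorted, so the
output is identical for any policy, worker count, or executor availability
— the central correctness property of a heterogeneous pipeline.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from .errors import ConfigError
from .geometry import MBB, PolygonF, extract_mbb
from .partition import (
    CandidatePair,
    GridSpec,
    TileConfig,
    canonical_tile,
    default_grid,
    index_filter,
    partition_fixed_grid,
)
from .refine import (
    CrossMatchResult,
    ExecutorKind,
    SamplingConfig,
    batch_refine,
    refine_pair_exact,
    refine_pair_pixel,
)
from .scaling import (
    Fallback,
    FallbackDecision,
    ScaledPair,
    ScalingConfig,
    scale_mbb,
    select_scaling_factor,
)

logger = logging.getLogger(__name__)

_MIN_PRIORITY = -math.inf


class TaskKind(str, Enum):
    PARSE = "parse"
    INDEX_FILTER = "index_filter"
    REFINE = "refine"


class Policy(str, Enum):
    FCFS = "fcfs"
    PQ = "pq"


@dataclass
class Task:
    """A schedulable unit of pipeline work. Parse and index/filter tasks
    always carry the minimum priority (CPU-only stages)."""

    kind: TaskKind
    payload: Callable[[], object]
    priority: float
    tile_id: tuple[int, int] | None
    seq: int = 0

    def __post_init__(self):
        if self.kind is not TaskKind.REFINE:
            self.priority = _MIN_PRIORITY


@dataclass(frozen=True)
class CostModelParams:
    """Workload statistics feeding the executor decision."""

    n_pairs: int = 0
    total_vertices: int = 0
    payload_bytes: int = 0
    est_pixel_work: int = 0


@dataclass(frozen=True)
class SchedulerConfig:
    policy: Policy = Policy.FCFS
    n_serial_workers: int = 1
    vectorized_executor: bool = True
    work_gain_coeff: float = 1.0
    transfer_cost_coeff: float = 1.0
    batch_overhead_bytes: float = 500_000.0
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "policy", Policy(self.policy))
        if self.n_serial_workers < 1:
            raise ConfigError("n_serial_workers must be >= 1")


_BYTES_PER_VERTEX = 16  # two float64 coordinates


def _overlap_pixels(a: MBB, b: MBB) -> int:
    ov = a.intersection(b)
    if ov is None:
        return 0
    return int(ov.xmax - ov.xmin) * int(ov.ymax - ov.ymin)


def estimate_parameters(
    pairs: Sequence[ScaledPair | CandidatePair], k_hint: int = 50
) -> CostModelParams:
    """Exact workload counts for a refine batch.

    ``est_pixel_work`` sums the pixel counts of the pairs' scaled-MBB
    overlaps. For not-yet-scaled candidates the boxes are scaled at
    ``k_hint`` (the smallest candidate factor) to get a comparable figure.
    """
    n_pairs = 0
    total_vertices = 0
    work = 0
    for pr in pairs:
        n_pairs += 1
        if isinstance(pr, ScaledPair):
            total_vertices += len(pr.poly_a.vertices) + len(pr.poly_b.vertices)
            work += _overlap_pixels(pr.mbb_a, pr.mbb_b)
        else:
            total_vertices += pr.v_count_a + pr.v_count_b
            work += _overlap_pixels(
                scale_mbb(pr.mbb_a, k_hint), scale_mbb(pr.mbb_b, k_hint)
            )
    return CostModelParams(
        n_pairs=n_pairs,
        total_vertices=total_vertices,
        payload_bytes=total_vertices * _BYTES_PER_VERTEX,
        est_pixel_work=work,
    )


def priority_score(params: CostModelParams, cfg: SchedulerConfig) -> float:
    """Estimated gain of the vectorized executor over serial: pixel work
    weighted by ``work_gain_coeff`` minus the transfer cost of the payload
    (plus a fixed per-batch setup overhead) weighted by
    ``transfer_cost_coeff``. Positive means vectorized pays off."""
    return cfg.work_gain_coeff * params.est_pixel_work - cfg.transfer_cost_coeff * (
        params.payload_bytes + cfg.batch_overhead_bytes
    )


def evaluate_executor(params: CostModelParams, cfg: SchedulerConfig) -> ExecutorKind:
    """Pick the refine executor: vectorized iff the priority score is
    positive (and a vectorized executor is available). Monotone in
    ``est_pixel_work``: more pixel work never flips vectorized to serial."""
    if cfg.vectorized_executor and priority_score(params, cfg) > 0:
        return ExecutorKind.VECTORIZED
    return ExecutorKind.SERIAL


def _ordered(tasks: list[Task], policy: Policy) -> list[Task]:
    if policy is Policy.PQ:
        heap = [(-t.priority, t.seq, t) for t in tasks]
        heapq.heapify(heap)
        return [heapq.heappop(heap)[2] for _ in range(len(heap))]
    return sorted(tasks, key=lambda t: t.seq)


def _execute_phase(
    tasks: list[Task],
    cfg: SchedulerConfig,
    dispatch_log: list[dict] | None,
) -> dict[int, object]:
    """Run one pipeline phase under the configured policy and worker count.

    Tasks are dequeued in policy order (logged), executed on the serial
    worker pool, and results keyed by task sequence number — execution
    order never influences results."""
    ordered = _ordered(tasks, cfg.policy)
    for t in ordered:
        rec = {
            "tile_id": t.tile_id,
            "kind": t.kind.value,
            "priority": t.priority,
            "executor": "serial-pool",
        }
        logger.debug(
            "dispatch tile=%s kind=%s priority=%s", t.tile_id, t.kind.value, t.priority
        )
        if dispatch_log is not None:
            dispatch_log.append(rec)
    if cfg.n_serial_workers == 1:
        return {t.seq: t.payload() for t in ordered}
    with ThreadPoolExecutor(max_workers=cfg.n_serial_workers) as pool:
        futures = {t.seq: pool.submit(t.payload) for t in ordered}
        return {seq: f.result() for seq, f in futures.items()}


def _refine_tile(
    candidates: list[CandidatePair],
    polygons_a: dict[object, PolygonF],
    polygons_b: dict[object, PolygonF],
    scaling_cfg: ScalingConfig,
    sampling_cfg: SamplingConfig,
    sched_cfg: SchedulerConfig,
    dispatch_log: list[dict] | None,
    tile_id: tuple[int, int],
) -> list[CrossMatchResult]:
    scaled: list[ScaledPair] = []
    fallbacks: list[FallbackDecision] = []
    for c in candidates:
        verdict = select_scaling_factor(polygons_a[c.id_a], polygons_b[c.id_b], scaling_cfg)
        if isinstance(verdict, ScaledPair):
            scaled.append(verdict)
        else:
            fallbacks.append(verdict)
    results: list[CrossMatchResult] = []
    if scaled:
        executor = evaluate_executor(estimate_parameters(scaled), sched_cfg)
        if dispatch_log is not None:
            dispatch_log.append(
                {"tile_id": tile_id, "kind": "refine-batch", "executor": executor.value,
                 "n_pairs": len(scaled)}
            )
        results.extend(batch_refine(scaled, executor, sampling_cfg))
    for fb in fallbacks:
        if fb.action is Fallback.EXACT_REFINER:
            results.append(refine_pair_exact(fb.poly_a, fb.poly_b, qualified=False))
        elif fb.action is Fallback.ACCEPT_LARGEST_K and fb.best is not None:
            r = refine_pair_pixel(fb.best)
            results.append(
                CrossMatchResult(**{**r.__dict__, "qualified": False})
            )
        # Fallback.REJECT: drop the pair
    return results


def run_query(
    dataset_a: Sequence[PolygonF],
    dataset_b: Sequence[PolygonF],
    scaling_cfg: ScalingConfig = ScalingConfig(),
    sampling_cfg: SamplingConfig = SamplingConfig(),
    sched_cfg: SchedulerConfig = SchedulerConfig(),
    grid: GridSpec | None = None,
    dispatch_log: list[dict] | None = None,
) -> list[CrossMatchResult]:
    """Cross-match two polygon datasets end to end.

    Both datasets are partitioned on a shared fixed grid, co-located tiles
    are filtered through the R-tree stage, surviving pairs are scaled and
    refined (pixel refiner for qualified pairs, exact clipping for
    fallbacks), and the deduplicated results are returned sorted by
    ``(id_a, id_b)``. Output is identical under every scheduling policy and
    worker count. Datasets with disjoint extents yield an empty result.
    """
    if not dataset_a or not dataset_b:
        raise ConfigError("run_query requires two non-empty datasets")
    if grid is None:
        ext = extract_mbb(dataset_a[0])
        for p in itertools.chain(dataset_a, dataset_b):
            ext = ext.union(extract_mbb(p))
        grid = default_grid(ext)
    seq = itertools.count()

    # phase 1: load / partition (CPU-only, minimum priority)
    parse_tasks = [
        Task(TaskKind.PARSE, lambda d=d: partition_fixed_grid(d, grid), _MIN_PRIORITY,
             None, seq=next(seq))
        for d in (dataset_a, dataset_b)
    ]
    parsed = _execute_phase(parse_tasks, sched_cfg, dispatch_log)
    tiles_a = {t.tile_id: t for t in parsed[parse_tasks[0].seq]}
    tiles_b = {t.tile_id: t for t in parsed[parse_tasks[1].seq]}

    # phase 2: index/filter co-located tiles (tiles missing a counterpart
    # produce no pairs and are skipped)
    shared = sorted(set(tiles_a) & set(tiles_b))
    filter_tasks = [
        Task(
            TaskKind.INDEX_FILTER,
            lambda ta=tiles_a[tid], tb=tiles_b[tid]: index_filter(ta, tb),
            _MIN_PRIORITY,
            tid,
            seq=next(seq),
        )
        for tid in shared
    ]
    filtered = _execute_phase(filter_tasks, sched_cfg, dispatch_log)

    # canonical-tile deduplication of replicated pairs
    per_tile: dict[tuple[int, int], list[CandidatePair]] = {}
    duplicates = 0
    for task in filter_tasks:
        for c in filtered[task.seq]:
            if canonical_tile(c.mbb_a, c.mbb_b, grid) == c.tile_id:
                per_tile.setdefault(c.tile_id, []).append(c)
            else:
                duplicates += 1
    logger.debug("filter: %d duplicate cross-tile pairs dropped", duplicates)

    # phase 3: refine, one task per tile, priority from the cost model
    lookup_a = {p.id: p for p in dataset_a}
    lookup_b = {p.id: p for p in dataset_b}
    k_hint = scaling_cfg.k_candidates[0]
    refine_tasks = []
    for tid in sorted(per_tile):
        cands = per_tile[tid]
        prio = priority_score(estimate_parameters(cands, k_hint), sched_cfg)
        refine_tasks.append(
            Task(
                TaskKind.REFINE,
                lambda cands=cands, tid=tid: _refine_tile(
                    cands, lookup_a, lookup_b, scaling_cfg, sampling_cfg,
                    sched_cfg, dispatch_log, tid,
                ),
                prio,
                tid,
                seq=next(seq),
            )
        )
    refined = _execute_phase(refine_tasks, sched_cfg, dispatch_log)

    results: dict[tuple, CrossMatchResult] = {}
    for task in refine_tasks:
        for r in refined[task.seq]:
            results.setdefault(r.pair_id, r)
    return [results[k] for k in sorted(results, key=lambda p: (str(p[0]), str(p[1])))]
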