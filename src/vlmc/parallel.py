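"""Partitioned k-mer enumeration over disjoint suffix ranges.

The tree is expanded serially for a configurable number of levels (the
root expansion stays serial: it is cheap relative to the subtrees);
every surviving range at the cut-off level becomes an independent task
that evaluates its whole subtree into a private buffer.  Buffers are
merged in deterministic task order, so the result is identical to
serial enumeration regardless of scheduling.  Tasks own disjoint
prefixes, hence no k-mer is ever produced twice, and oversubscription
(more tasks than workers) is allowed to absorb GC-content skew between
subtrees.
"""

from __future__ import annotations

from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import Corpus
from .suffix_counting import (
    KmerRecord,
    KmerTable,
    NodeRange,
    _root_record,
    evaluate_node,
    init_root_range,
)


class TaskError(RuntimeError):
    """A subtree task failed; names the owning context prefix."""


@dataclass
class TaskPlan:
    """Independent subtree tasks plus the serially emitted shallow records.

    ``tasks`` holds the level-``parallel_depth`` subtree roots that run
    concurrently; ``spawned_per_level`` counts the surviving ranges at
    every level 1..parallel_depth (at full fan-out on DNA these number
    4, 16, ... per level).
    """

    corpus: Corpus
    workspace: np.ndarray
    parallel_depth: int
    tasks: list[tuple[str, NodeRange]]
    preamble: list[KmerRecord]
    spawned_per_level: list[int]
    worker_limit: int | None = None

    @property
    def task_creations(self) -> int:
        """Total subtree spawns across all levels (e.g. 4+16 at depth 2)."""
        return sum(self.spawned_per_level)


def plan_tasks(
    corpus: Corpus,
    workspace: np.ndarray,
    min_count: int,
    max_depth: int,
    parallel_depth: int,
    worker_limit: int | None = None,
) -> TaskPlan:
    """Expand the first ``parallel_depth`` levels serially, emit tasks.

    Level 0 is the root node; the ranges surviving the support and
    depth gates at level ``parallel_depth`` become the tasks, ordered
    lexicographically by their path through the tree.
    """
    if parallel_depth < 0:
        raise ValueError("parallel_depth must be >= 0")
    preamble: list[KmerRecord] = [_root_record(corpus, workspace)]
    _, root = init_root_range(corpus)
    level: list[tuple[str, NodeRange]] = [("", root)]
    spawned: list[int] = []
    for _ in range(parallel_depth):
        nxt: list[tuple[str, NodeRange]] = []
        for ctx, node in level:
            recs, children = evaluate_node(corpus, workspace, node, ctx, max_depth)
            preamble.extend(r for r in recs if r.count >= min_count)
            for child, child_ctx in children:
                if child.size >= min_count and len(child_ctx) + 1 <= max_depth:
                    nxt.append((child_ctx, child))
        spawned.append(len(nxt))
        level = nxt
    return TaskPlan(
        corpus=corpus,
        workspace=workspace,
        parallel_depth=parallel_depth,
        tasks=level,
        preamble=preamble,
        spawned_per_level=spawned,
        worker_limit=worker_limit,
    )


def _evaluate_subtree(
    corpus: Corpus,
    workspace_slice: np.ndarray,
    node: NodeRange,
    context: str,
    min_count: int,
    max_depth: int,
) -> list[KmerRecord]:
    """Fully evaluate one subtree into a private record buffer."""
    buffer: list[KmerRecord] = []
    queue: deque[tuple[NodeRange, str]] = deque(
        [(NodeRange(0, node.size - 1, node.depth), context)]
    )
    while queue:
        rng, ctx = queue.popleft()
        recs, children = evaluate_node(corpus, workspace_slice, rng, ctx, max_depth)
        buffer.extend(recs)
        for child, child_ctx in children:
            if child.size >= min_count and len(child_ctx) + 1 <= max_depth:
                queue.append((child, child_ctx))
    return buffer


def run_partitioned(
    plan: TaskPlan,
    min_count: int,
    max_depth: int,
    workers: int | None = None,
) -> KmerTable:
    """Run every task with a private buffer and merge deterministically.

    The merged table equals the serial enumeration exactly; task
    failures propagate with the owning context prefix named.
    """
    workers = workers or plan.worker_limit

    def run_task(item: tuple[str, NodeRange]) -> list[KmerRecord]:
        ctx, node = item
        private = plan.workspace[node.left : node.right + 1].copy()
        try:
            return _evaluate_subtree(
                plan.corpus, private, node, ctx, min_count, max_depth
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise TaskError(f"subtree task under context {ctx!r} failed") from exc

    if plan.tasks:
        with ThreadPoolExecutor(max_workers=workers or len(plan.tasks)) as pool:
            buffers = list(pool.map(run_task, plan.tasks))
    else:
        buffers = []

    records: dict[str, KmerRecord] = {}
    for rec in plan.preamble:
        records[rec.context] = rec
    for buf in buffers:  # deterministic task order
        for rec in buf:
            records[rec.context] = rec
    return KmerTable(records=records, min_count=min_count, max_depth=max_depth)
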