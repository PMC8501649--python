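"""Supported k-mer enumeration via lazy evaluation of suffix ranges.

Instead of materialising a suffix tree, every unevaluated node is a
contiguous range of suffix start positions in a shared workspace array
(write-only top-down construction).  Evaluating a node computes the
longest common extension of its suffixes, emits one k-mer record per
extension character (expanding implicit nodes to unit-length edges),
counting-sorts the range by the next character, and yields one child
range per residue group.  A child range is pursued only while its size
meets the minimum count t and its context length stays within the
maximum depth L; occurrence counts are monotone under extension, so
pruning early loses nothing.

The enumeration result is an associative map from context strings to
their occurrence statistics -- the "store counts in a map, skip the
suffix links" construction variant.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import SENTINEL, SYMBOLS, Corpus


@dataclass
class NodeRange:
    """An unevaluated node: inclusive workspace range plus string depth.

    ``depth`` counts the characters already matched by every suffix in
    the range (the string depth of the parent context the range was
    derived under).
    """

    left: int
    right: int
    depth: int

    @property
    def size(self) -> int:
        return self.right - self.left + 1


@dataclass(frozen=True)
class KmerRecord:
    """A context w with N(w), per-symbol N(wσ) and terminal occurrences."""

    context: str
    count: int
    next_counts: tuple[int, int, int, int]
    terminal_count: int = 0

    def __post_init__(self):
        assert self.count == sum(self.next_counts) + self.terminal_count


@dataclass
class KmerTable:
    """Map from context string to :class:`KmerRecord` plus (t, L)."""

    records: dict[str, KmerRecord]
    min_count: int
    max_depth: int

    def __contains__(self, context: str) -> bool:
        return context in self.records

    def __getitem__(self, context: str) -> KmerRecord:
        return self.records[context]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KmerTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.min_count == other.min_count
            and self.max_depth == other.max_depth
        )


def init_root_range(corpus: Corpus) -> tuple[np.ndarray, NodeRange]:
    """Workspace of all residue start positions and the root range.

    Suffixes starting on a sentinel cell carry no information and are
    excluded up front.
    """
    workspace = np.flatnonzero(corpus.encoded != SENTINEL).astype(np.int64)
    return workspace, NodeRange(0, len(workspace) - 1, 0)


def _extension_codes(
    corpus: Corpus,
    positions: np.ndarray,
    depth: int,
    cap: int | None = None,
) -> list[int]:
    """Common extension of all suffixes beyond ``depth``, as codes.

    Stops at divergence or at any sentinel (a sentinel matches nothing,
    including another sentinel).  At most ``cap`` characters are
    examined when a cap is given.
    """
    text = corpus.encoded
    ext: list[int] = []
    off = depth
    while cap is None or len(ext) < cap:
        chars = text[positions + off]
        c0 = int(chars[0])
        if c0 == SENTINEL or not np.all(chars == c0):
            break
        ext.append(c0)
        off += 1
    return ext


def longest_common_extension(
    corpus: Corpus, workspace: np.ndarray, node: NodeRange
) -> str:
    """Maximal string by which every suffix in the range continues."""
    positions = workspace[node.left : node.right + 1]
    return "".join(SYMBOLS[c] for c in _extension_codes(corpus, positions, node.depth))


def sort_and_partition(
    corpus: Corpus, workspace: np.ndarray, node: NodeRange, depth: int
) -> tuple[dict[int, NodeRange], int]:
    """Counting-sort the range by the character at offset ``depth``.

    The workspace is permuted in place so suffixes are grouped A, C, G,
    T with terminal suffixes (sentinel at the offset) last; within each
    group the prior (position-ascending, longest-suffix-first) order is
    preserved.  Returns one child range per non-empty residue group plus
    the terminal count.  Child ranges keep ``depth`` as their recorded
    string depth; their branch symbol is re-derived by the child's own
    extension step.
    """
    positions = workspace[node.left : node.right + 1]
    chars = corpus.encoded[positions + depth]
    order = np.argsort(chars, kind="stable")
    workspace[node.left : node.right + 1] = positions[order]
    tallies = np.bincount(chars, minlength=5)
    children: dict[int, NodeRange] = {}
    lo = node.left
    for sym in range(4):
        n = int(tallies[sym])
        if n:
            children[sym] = NodeRange(lo, lo + n - 1, depth)
            lo += n
    return children, int(tallies[SENTINEL])


def evaluate_node(
    corpus: Corpus,
    workspace: np.ndarray,
    node: NodeRange,
    parent_context: str,
    max_depth: int | None = None,
) -> tuple[list[KmerRecord], list[tuple[NodeRange, str]]]:
    """Evaluate one suffix range under its parent context.

    Emits one record per character of the common extension: contexts
    interior to the extension put the whole range size on their single
    continuation symbol; the final context's next-symbol counts are the
    child-group sizes of the counting sort.  Emission truncates at
    context length ``max_depth``.  Returns the records together with
    the child ranges (paired with the context they extend) for further
    evaluation; support filtering is the caller's concern.
    """
    d = node.depth
    size = node.size
    positions = workspace[node.left : node.right + 1]
    cap = None if max_depth is None else max_depth - d + 1
    ext = _extension_codes(corpus, positions, d, cap)

    records: list[KmerRecord] = []
    truncated = max_depth is not None and len(ext) == cap
    n_emit = (max_depth - d) if truncated else len(ext)

    ctx = parent_context
    for i in range(n_emit):
        ctx = ctx + SYMBOLS[ext[i]]
        if i + 1 < len(ext):  # interior: single continuation symbol
            nxt = [0, 0, 0, 0]
            nxt[ext[i + 1]] = size
            records.append(KmerRecord(ctx, size, tuple(nxt), 0))

    if truncated:
        return records, []

    # Final (branching or leaf) context: counts from the counting sort.
    children, terminal = sort_and_partition(corpus, workspace, node, d + len(ext))
    nxt = [0, 0, 0, 0]
    for sym, child in children.items():
        nxt[sym] = child.size
    final_ctx = parent_context + "".join(SYMBOLS[c] for c in ext)
    if final_ctx:  # the root's own record is assembled by the caller
        records.append(KmerRecord(final_ctx, size, tuple(nxt), terminal))
    return records, [(child, final_ctx) for child in children.values()]


def _root_record(corpus: Corpus, workspace: np.ndarray) -> KmerRecord:
    tallies = np.bincount(corpus.encoded[workspace], minlength=4)
    nxt = tuple(int(x) for x in tallies[:4])
    return KmerRecord("", int(sum(nxt)), nxt, 0)


def count_supported_kmers(
    corpus: Corpus,
    min_count: int,
    max_depth: int,
    parallel_depth: int = 0,
    workers: int | None = None,
) -> KmerTable:
    """All k-mers w of the corpus with N(w) >= min_count, |w| <= max_depth.

    Breadth-first lazy evaluation from the root; a child range is
    pursued only if its size passes the support threshold and its
    context stays within the depth cap.  The root record (empty
    context, count = number of residue positions, next counts = residue
    frequencies) is always retained.  With ``parallel_depth`` > 0 the
    work is partitioned into independent subtree tasks; the result is
    identical to serial execution.
    """
    if min_count < 1 or max_depth < 1:
        raise ValueError("min_count and max_depth must be >= 1")
    if parallel_depth > 0:
        from .parallel import plan_tasks, run_partitioned

        workspace, _ = init_root_range(corpus)
        plan = plan_tasks(
            corpus, workspace, min_count, max_depth, parallel_depth, workers
        )
        return run_partitioned(plan, min_count, max_depth)

    workspace, root = init_root_range(corpus)
    records: dict[str, KmerRecord] = {}
    rr = _root_record(corpus, workspace)
    records[rr.context] = rr
    queue: deque[tuple[NodeRange, str]] = deque([(root, "")])
    while queue:
        node, ctx = queue.popleft()
        recs, children = evaluate_node(corpus, workspace, node, ctx, max_depth)
        for rec in recs:
            # The root's own extension chain is the one place a record
            # below the support threshold can be emitted.
            if rec.count >= min_count:
                records[rec.context] = rec
        for child, child_ctx in children:
            if child.size >= min_count and len(child_ctx) + 1 <= max_depth:
                queue.append((child, child_ctx))
    return KmerTable(records=records, min_count=min_count, max_depth=max_depth)
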