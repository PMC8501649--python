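"""Probabilistic suffix trees: probability estimation, KL pruning, I/O.

A variable-length Markov chain is stored as a suffix-closed map from
context strings to k-mer records.  Next-symbol probabilities use +1
pseudo-counts on each of the four extension counts so no probability is
ever zero.  Similarity pruning removes, bottom-up, every childless
context whose weighted Kullback-Leibler divergence from its parent
(one symbol shorter, oldest symbol dropped) falls below a threshold K.
The default K is half the chi-squared critical value at 3 degrees of
freedom and p = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import SYMBOLS, Corpus
from .suffix_counting import KmerRecord, KmerTable, count_supported_kmers

#: Half the 95th percentile of chi2 with |Sigma|-1 = 3 degrees of freedom.
DEFAULT_KL_THRESHOLD = 3.9075

_FORMAT_HEADER = "#vlmc-tsv v1"


@dataclass
class VLMC:
    """A trained variable-length Markov chain.

    ``train_length`` is the number of scored positions of the training
    corpus (residues only; sentinels and masked bases excluded).
    """

    nodes: dict[str, KmerRecord]
    min_count: int
    max_depth: int
    kl_threshold: float
    train_length: int
    alphabet: str = SYMBOLS

    def __contains__(self, context: str) -> bool:
        return context in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VLMC):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.min_count == other.min_count
            and self.max_depth == other.max_depth
            and self.kl_threshold == other.kl_threshold
            and self.train_length == other.train_length
        )


@dataclass
class PruneReport:
    """Contexts removed by similarity pruning and every examined delta."""

    removed: set[str] = field(default_factory=set)
    delta_values: dict[str, float] = field(default_factory=dict)


def next_symbol_probabilities(record: KmerRecord) -> np.ndarray:
    """Pseudo-counted next-symbol estimates (N(wσ)+1) / (Σ N(wc)+4)."""
    counts = np.asarray(record.next_counts, dtype=np.float64)
    return (counts + 1.0) / (counts.sum() + 4.0)


def parent_context(context: str) -> str:
    """Drop the leftmost (oldest) symbol; the parent in the suffix tree."""
    if not context:
        raise ValueError("the root context has no parent")
    return context[1:]


def kl_delta(child: KmerRecord, parent: KmerRecord) -> float:
    """Weighted KL divergence Δ = N(cw) Σ_σ p̂(σ|cw) ln(p̂(σ|cw)/p̂(σ|w)).

    The multiplier is the raw occurrence count; pseudo-counts enter only
    through the probability estimates.  Natural log throughout.
    """
    p = next_symbol_probabilities(child)
    q = next_symbol_probabilities(parent)
    return float(child.count * np.sum(p * np.log(p / q)))


def similarity_prune(
    table: KmerTable, kl_threshold: float = DEFAULT_KL_THRESHOLD
) -> tuple[VLMC, PruneReport]:
    """Remove contexts too similar to their parents, leaf-first.

    A context is removed iff it currently has no surviving child
    (σ·w for σ in the alphabet) and Δ < K; processing contexts from the
    deepest up makes one pass reach the fixpoint, because removing cw
    can only unlock its strictly shorter parent w.  The root is never
    removed and the result stays suffix-closed.
    """
    nodes = dict(table.records)
    report = PruneReport()
    for ctx in sorted(nodes, key=lambda c: (-len(c), c)):
        if not ctx:
            continue
        delta = kl_delta(nodes[ctx], nodes[parent_context(ctx)])
        report.delta_values[ctx] = delta
        has_child = any(sym + ctx in nodes for sym in SYMBOLS)
        if not has_child and delta < kl_threshold:
            del nodes[ctx]
            report.removed.add(ctx)
    train_length = nodes[""].count
    model = VLMC(
        nodes=nodes,
        min_count=table.min_count,
        max_depth=table.max_depth,
        kl_threshold=kl_threshold,
        train_length=train_length,
    )
    return model, report


def train(
    corpus: Corpus,
    min_count: int,
    max_depth: int,
    kl_threshold: float = DEFAULT_KL_THRESHOLD,
    parallel_depth: int = 0,
    workers: int | None = None,
) -> tuple[VLMC, PruneReport]:
    """Count supported k-mers, then similarity-prune: one call training."""
    table = count_supported_kmers(
        corpus, min_count, max_depth, parallel_depth=parallel_depth, workers=workers
    )
    return similarity_prune(table, kl_threshold)


def leaves(model: VLMC) -> set[str]:
    """Contexts without any stored single-symbol extension σ·w.

    The root counts only when it is the sole node, which falls out of
    the definition because suffix-closure puts every 1-mer under the
    root.
    """
    return {
        ctx
        for ctx in model.nodes
        if not any(sym + ctx in model.nodes for sym in SYMBOLS)
    }


def _format_float(x: float) -> str:
    return repr(float(x))


def write_model(model: VLMC, path: str | Path) -> None:
    """Serialize a model as TSV; the root context is the token '*'."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(
            f"#params t={model.min_count} L={model.max_depth} "
            f"K={_format_float(model.kl_threshold)} "
            f"train_length={model.train_length}\n"
        )
        fh.write("context\tcount\tnA\tnC\tnG\tnT\tnTerm\n")
        for ctx in sorted(model.nodes, key=lambda c: (len(c), c)):
            rec = model.nodes[ctx]
            token = ctx if ctx else "*"
            nxt = "\t".join(str(n) for n in rec.next_counts)
            fh.write(f"{token}\t{rec.count}\t{nxt}\t{rec.terminal_count}\n")


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or has the wrong version."""


def read_model(path: str | Path) -> VLMC:
    """Read a model written by :func:`write_model`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _FORMAT_HEADER:
        raise ModelFormatError(
            f"{path}: line 1: expected header {_FORMAT_HEADER!r}"
        )
    if len(lines) < 2 or not lines[1].startswith("#params "):
        raise ModelFormatError(f"{path}: line 2: missing #params header")
    params: dict[str, str] = {}
    for item in lines[1][len("#params ") :].split():
        key, _, value = item.partition("=")
        params[key] = value
    try:
        t = int(params["t"])
        L = int(params["L"])
        K = float(params["K"])
        train_length = int(params["train_length"])
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"{path}: line 2: bad #params header: {exc}")
    nodes: dict[str, KmerRecord] = {}
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ModelFormatError(
                f"{path}: line {lineno}: expected 7 columns, got {len(fields)}"
            )
        token = fields[0]
        ctx = "" if token == "*" else token
        if any(ch not in SYMBOLS for ch in ctx):
            raise ModelFormatError(f"{path}: line {lineno}: bad context {token!r}")
        try:
            count = int(fields[1])
            next_counts = tuple(int(x) for x in fields[2:6])
            terminal = int(fields[6])
        except ValueError as exc:
            raise ModelFormatError(f"{path}: line {lineno}: bad count column: {exc}")
        if count != sum(next_counts) + terminal:
            raise ModelFormatError(
                f"{path}: line {lineno}: count does not equal "
                "next-symbol counts plus terminal count"
            )
        nodes[ctx] = KmerRecord(ctx, count, next_counts, terminal)
    if "" not in nodes:
        raise ModelFormatError(f"{path}: missing root context row")
    return VLMC(
        nodes=nodes,
        min_count=t,
        max_depth=L,
        kl_threshold=K,
        train_length=train_length,
    )
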