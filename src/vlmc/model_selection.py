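"""BIC model selection over the (min count, max depth) grid.

BIC := card(M)·ln|S| − 2·ln P_M(S), where |S| is the number of scored
training positions and card(M) = (|Σ|−1)·L(M) counts one free
parameter set per leaf of the probabilistic suffix tree (internal
contexts are redundant: they can always be extended to a more specific
one).  The grid search trains one pruned model per (t, L) pair,
re-using the k-mer counts of the largest depth by truncation, and the
cell with the lowest BIC is the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .model import DEFAULT_KL_THRESHOLD, VLMC, leaves, similarity_prune
from .scoring import negative_log_likelihood
from .sequence_io import Corpus
from .suffix_counting import KmerTable, count_supported_kmers


class BicResult(NamedTuple):
    log_likelihood: float
    card: int
    bic: float


@dataclass
class GridResult:
    """Per-(t, L) statistics and the BIC-optimal cell."""

    table: pd.DataFrame
    optimum: tuple[int, int]


def bic_score(model: VLMC, corpus: Corpus) -> BicResult:
    """Score the training corpus under the pruned model and apply BIC."""
    total_nll = 0.0
    scored = 0
    for record in corpus.decode():
        res = negative_log_likelihood(model, record)
        total_nll += res.total_nll
        scored += res.positions_scored
    log_likelihood = -total_nll
    card = (len(model.alphabet) - 1) * len(leaves(model))
    bic = card * math.log(scored) - 2.0 * log_likelihood
    return BicResult(log_likelihood=log_likelihood, card=card, bic=bic)


def _truncate(table: KmerTable, max_depth: int) -> KmerTable:
    """Restrict a counted table to contexts of length <= max_depth.

    Valid because every record's counts are independent of the depth
    cap; this is how the grid search re-uses one counting pass.
    """
    if max_depth >= table.max_depth:
        return table
    return KmerTable(
        records={w: r for w, r in table.records.items() if len(w) <= max_depth},
        min_count=table.min_count,
        max_depth=max_depth,
    )


def rare_kmer_frequency(model: VLMC, quantile: float = 0.05) -> int:
    """Count of the q-quantile least common context at the maximal depth.

    Takes the stored contexts at the deepest level present, sorts their
    counts ascending, and returns the element at floor(q·(n−1))
    (lower interpolation).
    """
    depths = [len(w) for w in model.nodes if w]
    if not depths:
        raise ValueError("model has no non-root context")
    deepest = max(depths)
    counts = sorted(r.count for w, r in model.nodes.items() if len(w) == deepest)
    idx = math.floor(quantile * (len(counts) - 1))
    return counts[idx]


def grid_search(
    corpus: Corpus,
    min_counts: Sequence[int],
    max_depths: Sequence[int],
    kl_threshold: float = DEFAULT_KL_THRESHOLD,
    parallel_depth: int = 0,
    workers: int | None = None,
) -> GridResult:
    """Train and BIC-score one model per (min count, max depth) cell.

    Deterministic: rows are ordered by (t, L); at equal BIC the optimum
    prefers the smaller depth, then the larger min count (the simpler
    model).
    """
    if not min_counts or not max_depths:
        raise ValueError("grids must be non-empty")
    t_grid = sorted(set(int(t) for t in min_counts))
    l_grid = sorted(set(int(L) for L in max_depths))
    rows = []
    for t in t_grid:
        full = count_supported_kmers(
            corpus, t, max(l_grid), parallel_depth=parallel_depth, workers=workers
        )
        for L in l_grid:
            model, _ = similarity_prune(_truncate(full, L), kl_threshold)
            res = bic_score(model, corpus)
            rare = rare_kmer_frequency(model) if len(model) > 1 else model.nodes[""].count
            rows.append(
                {
                    "t": t,
                    "L": L,
                    "contexts": len(model),
                    "leaves": len(leaves(model)),
                    "card": res.card,
                    "logL": res.log_likelihood,
                    "bic": res.bic,
                    "rare5pct": rare,
                }
            )
    table = pd.DataFrame(rows)
    # Optimum: minimal BIC; ties broken by smaller L, then larger t.
    best = table.sort_values(["bic", "L", "t"], ascending=[True, True, False]).iloc[0]
    return GridResult(table=table, optimum=(int(best["t"]), int(best["L"])))
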