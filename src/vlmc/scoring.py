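"""Negative log-likelihood scoring of sequences under a trained model.

Each position is scored with the longest stored suffix of its history
(capped at the model's maximum depth); the root always matches, so the
first positions of a sequence fall back to the best available shorter
context.  Non-ACGT characters are skipped and reset the history, the
same convention the training encoder applies with sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import VLMC, next_symbol_probabilities
from .sequence_io import SYMBOLS

_CODE = {sym: i for i, sym in enumerate(SYMBOLS)}


@dataclass(frozen=True)
class ScoreResult:
    total_nll: float
    positions_scored: int

    @property
    def nll_per_char(self) -> float:
        return self.total_nll / self.positions_scored if self.positions_scored else 0.0

    def __add__(self, other: "ScoreResult") -> "ScoreResult":
        return ScoreResult(
            self.total_nll + other.total_nll,
            self.positions_scored + other.positions_scored,
        )


def longest_matching_context(model: VLMC, history: str) -> str:
    """Longest suffix of the (depth-capped) history stored in the model."""
    h = history[-model.max_depth :] if model.max_depth < len(history) else history
    for start in range(len(h) + 1):
        if h[start:] in model.nodes:
            return h[start:]
    return ""  # unreachable: the root context matches everything


def _log_prob_rows(model: VLMC) -> dict[str, np.ndarray]:
    return {
        ctx: np.log(next_symbol_probabilities(rec))
        for ctx, rec in model.nodes.items()
    }


def negative_log_likelihood(model: VLMC, sequence: str) -> ScoreResult:
    """Score a residue string: -Σ_t ln p̂(x_t | longest matching context).

    Positions holding non-ACGT characters are not scored and reset the
    history window.
    """
    log_rows = _log_prob_rows(model)
    cache: dict[str, np.ndarray] = {}
    use_cache = model.max_depth <= 12  # keeps the window cache small
    L = model.max_depth
    history = ""
    total = 0.0
    scored = 0
    for ch in sequence.upper():
        code = _CODE.get(ch)
        if code is None:
            history = ""
            continue
        row = cache.get(history)
        if row is None:
            row = log_rows[longest_matching_context(model, history)]
            if use_cache:
                cache[history] = row
        total -= float(row[code])
        scored += 1
        history = (history + ch)[-L:] if len(history) >= L else history + ch
    return ScoreResult(total_nll=total, positions_scored=scored)


def score_records(
    model: VLMC, records: list[tuple[str, str]], split: int = 1
) -> list[tuple[str, ScoreResult]]:
    """Score FASTA records; ``split`` > 1 scores each record in chunks.

    Chunk boundaries reset the history, mirroring the piecewise scoring
    used for parallel evaluation, so the per-record totals are the sums
    of the chunk scores.
    """
    out = []
    for ident, seq in records:
        if split <= 1:
            out.append((ident, negative_log_likelihood(model, seq)))
            continue
        n = len(seq)
        step = max(1, -(-n // split))
        acc = ScoreResult(0.0, 0)
        for i in range(0, n, step):
            acc = acc + negative_log_likelihood(model, seq[i : i + step])
        out.append((ident, acc))
    return out
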