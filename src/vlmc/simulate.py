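"""Ground-truth context-tree generators and brute-force oracles.

The generator draws a suffix-closed context tree with exact next-symbol
distributions and samples sequences from it, so that training can be
checked for exact recovery of the context set.  An optional floor on
the Kullback-Leibler divergence between every context and its parent
keeps the generator identifiable: contexts indistinguishable from
their parent could never survive similarity pruning.

The module also houses the quadratic-time sliding-window k-mer counter
used as the independent oracle for the lazy suffix-range enumeration.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .sequence_io import SYMBOLS
from .suffix_counting import KmerRecord

_CODE = {sym: i for i, sym in enumerate(SYMBOLS)}


@dataclass
class GeneratorVLMC:
    """A known context tree: exact distributions per context."""

    probabilities: dict[str, np.ndarray]
    max_order: int

    @property
    def contexts(self) -> set[str]:
        return set(self.probabilities)

    def longest_context(self, history: str) -> str:
        h = history[-self.max_order :]
        for start in range(len(h) + 1):
            if h[start:] in self.probabilities:
                return h[start:]
        return ""


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * np.log(p / q)))


def random_generator(
    seed: int,
    max_order: int,
    kl_floor: float = 0.0,
    max_retries: int = 10_000,
) -> GeneratorVLMC:
    """Draw a full context tree of the given order, reproducibly.

    Distributions are Dirichlet(1,1,1,1) draws; each child distribution
    is resampled until its KL divergence from its parent reaches
    ``kl_floor``.  Raises after ``max_retries`` rejections, which only
    happens for infeasibly large floors.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if kl_floor < 0:
        raise ValueError("kl_floor must be >= 0")
    rng = np.random.default_rng(seed)
    probs: dict[str, np.ndarray] = {"": rng.dirichlet(np.ones(4))}
    for order in range(1, max_order + 1):
        for combo in product(SYMBOLS, repeat=order):
            ctx = "".join(combo)
            parent = probs[ctx[1:]]
            for _ in range(max_retries):
                cand = rng.dirichlet(np.ones(4))
                if _kl(cand, parent) >= kl_floor:
                    probs[ctx] = cand
                    break
            else:
                raise ValueError(
                    f"could not reach KL floor {kl_floor} for context {ctx!r} "
                    f"after {max_retries} draws"
                )
    return GeneratorVLMC(probabilities=probs, max_order=max_order)


def sample_sequence(gen: GeneratorVLMC, n: int, seed: int) -> str:
    """Sample n residues from the generator's longest-matching context."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    uniforms = rng.random(n)
    # Cumulative rows per reachable history for fast repeated lookup.
    cum_cache: dict[str, list[float]] = {}

    def cum_for(history: str) -> list[float]:
        row = cum_cache.get(history)
        if row is None:
            row = list(np.cumsum(gen.probabilities[gen.longest_context(history)]))
            cum_cache[history] = row
        return row

    out = []
    history = ""
    order = gen.max_order
    for u in uniforms:
        sym = SYMBOLS[min(bisect_right(cum_for(history), u), 3)]
        out.append(sym)
        history = (history + sym)[-order:] if len(history) >= order else history + sym
    return "".join(out)


def brute_force_kmer_counts(
    sequence: str | list[str], max_depth: int
) -> dict[str, KmerRecord]:
    """Sliding-window counts of every substring of length <= max_depth.

    The independent, quadratic-time reference for the lazy suffix-range
    enumeration.  Non-ACGT characters break the window exactly like
    sentinels: an occurrence whose next position is a break or the end
    of a record counts as terminal.  Includes the empty (root) context,
    whose next-symbol counts are the residue frequencies.
    """
    records = [sequence] if isinstance(sequence, str) else list(sequence)
    counts: dict[str, int] = {"": 0}
    nexts: dict[str, list[int]] = {"": [0, 0, 0, 0]}
    terms: dict[str, int] = {"": 0}

    def add(w: str, follower: int | None) -> None:
        counts[w] = counts.get(w, 0) + 1
        if w not in nexts:
            nexts[w] = [0, 0, 0, 0]
            terms[w] = 0
        if follower is None:
            terms[w] += 1
        else:
            nexts[w][follower] += 1

    for rec in records:
        # Split into maximal ACGT runs; windows never cross a break.
        run = []
        for ch in rec.upper() + "$":
            code = _CODE.get(ch)
            if code is not None:
                run.append(ch)
                continue
            text = "".join(run)
            run = []
            for i in range(len(text)):
                counts[""] += 1
                nexts[""][_CODE[text[i]]] += 1
                for k in range(1, max_depth + 1):
                    if i + k > len(text):
                        break
                    w = text[i : i + k]
                    follower = (
                        _CODE[text[i + k]] if i + k < len(text) else None
                    )
                    add(w, follower)
    if counts[""] == 0:  # no residue at all
        return {}
    return {
        w: KmerRecord(w, counts[w], tuple(nexts[w]), terms[w]) for w in counts
    }


def write_generator(gen: GeneratorVLMC, path: str | Path) -> None:
    """Dump a generator's exact probabilities as TSV."""
    with open(path, "w") as fh:
        fh.write("#vlmc-generator v1\n")
        fh.write(f"#max_order {gen.max_order}\n")
        fh.write("context\tpA\tpC\tpG\tpT\n")
        for ctx in sorted(gen.probabilities, key=lambda c: (len(c), c)):
            token = ctx if ctx else "*"
            row = "\t".join(repr(float(p)) for p in gen.probabilities[ctx])
            fh.write(f"{token}\t{row}\n")
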