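"""FASTA input and integer encoding of DNA sequences.

Sequences are encoded over the alphabet A, C, G, T plus one sentinel
symbol.  The sentinel terminates every record and replaces every
ambiguous character (N, other IUPAC codes, gaps), so that no k-mer
window ever spans a record boundary or a masked base.  Downstream
modules rely on the convention that a sentinel matches nothing --
including another sentinel -- when comparing characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Residue symbols in fixed order; the order drives counting-sort bucket
#: order and the column order of the model file.
SYMBOLS = "ACGT"

#: Integer codes: A=0, C=1, G=2, T=3; the sentinel is 4.
SENTINEL = 4

A, C, G, T = range(4)

_ENCODE_LUT = np.full(256, SENTINEL, dtype=np.int8)
for _i, _ch in enumerate(SYMBOLS):
    _ENCODE_LUT[ord(_ch)] = _i
    _ENCODE_LUT[ord(_ch.lower())] = _i


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


@dataclass(frozen=True)
class Corpus:
    """Encoded training text with record boundaries.

    Attributes
    ----------
    encoded:
        int8 array, one cell per input position plus one sentinel cell
        terminating each record.  Residues hold codes 0..3, every other
        cell holds ``SENTINEL``.
    record_lengths:
        Original length (in input characters, including masked ones) of
        each record, in file order.
    """

    encoded: np.ndarray
    record_lengths: tuple[int, ...] = field(default=())

    @property
    def record_count(self) -> int:
        return len(self.record_lengths)

    @property
    def input_length(self) -> int:
        """Total input characters, including masked (non-ACGT) ones."""
        return int(sum(self.record_lengths))

    @property
    def valid_positions(self) -> int:
        """Number of cells holding a residue symbol."""
        return int(np.count_nonzero(self.encoded != SENTINEL))

    def decode(self) -> list[str]:
        """Recover the records; every masked input character becomes 'N'."""
        out = []
        start = 0
        for n in self.record_lengths:
            chunk = self.encoded[start : start + n]
            out.append("".join("ACGTN"[c] for c in chunk))
            start += n + 1  # skip the terminating sentinel
        return out


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(identifier, residue string)`` pairs.

    The identifier is the header up to the first whitespace; sequence
    lines are concatenated and upper-cased.  Raises
    :class:`FastaParseError` (naming the offending line) for an empty
    file or a file whose first non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: line 1: empty FASTA file")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise FastaParseError(f"{path}: line 1: no FASTA records found")
    return records


def encode_corpus(records: Iterable[str] | str) -> Corpus:
    """Encode residue strings into one sentinel-separated corpus.

    Every record is terminated by a sentinel cell and every non-ACGT
    character is replaced by a sentinel cell, so no k-mer spans a record
    boundary or a masked base.
    """
    if isinstance(records, str):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("encode_corpus requires at least one record")
    parts = []
    lengths = []
    for rec in records:
        codes = _ENCODE_LUT[np.frombuffer(rec.encode("ascii"), dtype=np.uint8)]
        parts.append(codes)
        parts.append(np.array([SENTINEL], dtype=np.int8))
        lengths.append(len(rec))
    encoded = np.concatenate(parts) if parts else np.array([], dtype=np.int8)
    corpus = Corpus(encoded=encoded, record_lengths=tuple(lengths))
    if corpus.valid_positions == 0:
        raise ValueError("corpus contains no valid ACGT residue")
    return corpus


def composition_stats(corpus: Corpus) -> dict:
    """Residue counts, GC percentage and length of a corpus.

    ``gc_percent`` uses the non-ambiguous denominator A+C+G+T;
    ``length`` counts all input characters including masked ones and is
    reported separately from ``valid_positions``.
    """
    tallies = np.bincount(corpus.encoded[corpus.encoded != SENTINEL], minlength=4)
    counts = {sym: int(tallies[i]) for i, sym in enumerate(SYMBOLS)}
    total = int(tallies.sum())
    gc = round(100.0 * (counts["G"] + counts["C"]) / total, 2) if total else 0.0
    return {
        "counts": counts,
        "gc_percent": gc,
        "length": corpus.input_length,
        "valid_positions": total,
    }


def decode_symbols(codes: Sequence[int]) -> str:
    """Render residue codes as a string (sentinel not allowed)."""
    return "".join(SYMBOLS[c] for c in codes)
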