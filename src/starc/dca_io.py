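"""Readers for direct-coupling score files and sequence input.

Four dialects are understood, covering the common DCA programs:

``evcouplings``
    Pair list ``i res_i j res_j score`` (whitespace or comma separated).
    Residue letters, when present, are validated against the query.
``psicov``
    Pair list ``i j lo hi score`` — the score is the last column.
``gaussdca``
    Pair list ``i j score``.
``ccmpred``
    A raw ell x ell score matrix, one row per line; the upper triangle
    supplies the pair scores.

All positions are 1-based in files and reports.  The canonical in-memory
form is the pair-record list, from which any pair-list dialect can be
re-emitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "DCRecord",
    "ScoredPairArray",
    "PatternSet",
    "parse_dc_scores",
    "write_evcouplings",
    "build_array",
    "pattern_pairs",
    "read_fasta",
]

DIALECTS = ("evcouplings", "psicov", "gaussdca", "ccmpred")


@dataclass(frozen=True, order=True)
class DCRecord:
    """One column pair with its direct-coupling score (i < j, 1-based)."""

    i: int
    j: int
    score: float

    def __post_init__(self):
        if not 1 <= self.i < self.j:
            raise ValueError(f"require 1 <= i < j, got i={self.i}, j={self.j}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for pair ({self.i}, {self.j})")


def _split(line: str) -> list[str]:
    return line.replace(",", " ").split()


def parse_dc_scores(file, dialect: str, query: str | None = None) -> list[DCRecord]:
    """Parse a DC score file into i<j pair records.

    Malformed lines raise with their line number; duplicated pairs keep the
    first occurrence with a warning; for the evcouplings dialect a residue
    letter that contradicts the query is a hard error.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = Path(file).read_text() if not hasattr(file, "read") else file.read()
    lines = text.splitlines()
    if dialect == "ccmpred":
        return _parse_matrix(lines, query)
    records: list[DCRecord] = []
    seen = set()
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = _split(line)
        try:
            if dialect == "evcouplings":
                i, ai, j, aj, score = (
                    int(parts[0]),
                    parts[1],
                    int(parts[2]),
                    parts[3],
                    float(parts[4]),
                )
            elif dialect == "psicov":
                i, j, score = int(parts[0]), int(parts[1]), float(parts[-1])
                ai = aj = None
            else:  # gaussdca
                if len(parts) != 3:
                    raise ValueError("expected 3 columns")
                i, j, score = int(parts[0]), int(parts[1]), float(parts[2])
                ai = aj = None
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{file}: malformed {dialect} line {ln}: {raw!r}") from exc
        if i > j:
            i, j = j, i
            ai, aj = aj, ai
        if query is not None and dialect == "evcouplings":
            for pos, letter in ((i, ai), (j, aj)):
                if letter and letter != "-" and pos <= len(query):
                    if query[pos - 1].upper() != letter.upper():
                        raise ValueError(
                            f"{file}: line {ln}: residue {letter} at position "
                            f"{pos} disagrees with query {query[pos - 1]}"
                        )
        if (i, j) in seen:
            warnings.warn(
                f"duplicate pair ({i}, {j}) at line {ln}; keeping first",
                stacklevel=2,
            )
            continue
        seen.add((i, j))
        records.append(DCRecord(i=i, j=j, score=score))
    return records


def _parse_matrix(lines: list[str], query: str | None) -> list[DCRecord]:
    rows = []
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        try:
            rows.append([float(v) for v in _split(raw)])
        except ValueError as exc:
            raise ValueError(f"malformed matrix line {ln}: {raw!r}") from exc
    M = np.asarray(rows)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"score matrix is not square: shape {M.shape}")
    n = M.shape[0]
    if query is not None and n != len(query):
        raise ValueError(
            f"matrix dimension {n} does not match query length {len(query)}"
        )
    return [
        DCRecord(i=i + 1, j=j + 1, score=float(M[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
    ]


def write_evcouplings(records, query: str | None = None) -> str:
    """Emit records as evcouplings-style ``i res_i j res_j score`` lines."""

    def res(pos):
        if query is None or pos > len(query):
            return "-"
        return query[pos - 1]

    return "".join(
        f"{r.i} {res(r.i)} {r.j} {res(r.j)} {r.score:.6f}\n" for r in records
    )


@dataclass(frozen=True)
class ScoredPairArray:
    """Pair records sorted by descending score; the array the statistics run on.

    ``ell`` is the query/MSA length in columns; ties in score break by
    (i, j) lexicographic order so the array is strictly ordered.
    """

    records: tuple
    ell: int
    query: str | None = None

    @property
    def L(self) -> int:
        return len(self.records)

    def __post_init__(self):
        if self.L > self.ell * (self.ell - 1) // 2:
            raise ValueError("more pairs than ell*(ell-1)/2 allows")


def build_array(records, query: str, m: int = 5) -> ScoredPairArray:
    """Filter by sequence separation and sort into the scored pair array.

    A pair (i, j) is retained when at least m residues intervene, i.e.
    j - i - 1 >= m.  Sorting is by descending score, ties by (i, j).
    """
    ell = len(query)
    for r in records:
        if r.j > ell:
            raise ValueError(f"pair ({r.i}, {r.j}) outside query of length {ell}")
    kept = [r for r in records if r.j - r.i - 1 >= m]
    if not kept:
        raise ValueError("no pairs left after separation filtering")
    kept.sort(key=lambda r: (-r.score, r.i, r.j))
    return ScoredPairArray(records=tuple(kept), ell=ell, query=query)


@dataclass(frozen=True)
class PatternSet:
    """Pattern residue positions (e.g. family-distinctive positions found by
    Bayesian pattern partitioning), ordered by decreasing pattern score."""

    positions: tuple

    def __post_init__(self):
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("pattern positions must be unique")
        if any(p < 1 for p in self.positions):
            raise ValueError("pattern positions are 1-based")


def pattern_pairs(patterns: PatternSet, m: int = 0) -> set:
    """All unordered pattern-position pairs passing the separation filter.

    These serve as an alternative distinguished set; no distance ranking is
    available for them, so downstream scoring omits the ball-in-urn term.
    """
    pos = sorted(patterns.positions)
    if len(pos) < 2:
        raise ValueError("need at least two pattern positions")
    return {
        (a, b)
        for k, a in enumerate(pos)
        for b in pos[k + 1 :]
        if b - a - 1 >= m
    }


def read_fasta(file, alignment: bool = False):
    """Read FASTA into [(id, sequence)]; gaps are preserved.

    With ``alignment=True`` all sequences must have equal length.
    """
    entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(file), "fasta")]
    if not entries:
        raise ValueError(f"no FASTA records in {file}")
    if alignment:
        width = len(entries[0][1])
        for rid, seq in entries:
            if len(seq) != width:
                raise ValueError(f"ragged alignment: {rid} has length {len(seq)}")
    return entries
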