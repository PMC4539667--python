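"""Per-sequence composition statistics.

Implements the two coordinates of the GC-content / G/C-stretch dot plot —
the GC fraction of a coding sequence and the summary statistics of its
maximal G/C stretches (runs of at least ``k`` consecutive G or C bases,
default ``k = 3``) — plus a pattern-based scanner for putative G-quadruplex
motifs (four or more G-tracts separated by short loops).

Coordinates are 0-based, half-open throughout.  Ambiguity codes (including
``S``, G-or-C) neither extend stretches nor enter the GC numerator or
denominator; this keeps every statistic a deterministic function of the
unambiguous bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

from .seqio import SeqRecordMeta

_STRONG = frozenset("GC")

# Full IUPAC complement map; preserves the G/C (strong) base class.
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


@dataclass(frozen=True)
class StretchInterval:
    """A maximal run of >= k consecutive G or C bases, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CompositionMetrics:
    """The per-sequence quantities plotted in a GC% vs stretch-length screen.

    ``mean_stretch_len`` is ``None`` (missing, not zero) when the sequence
    has no stretch of length >= k; ``max_stretch_len`` is then 0.
    """

    id: str
    length_nt: int
    gc_fraction: float
    n_stretches: int
    mean_stretch_len: float | None
    max_stretch_len: int
    total_stretch_nt: int
    gene: str | None = None
    species: str | None = None
    group: str | None = None


@dataclass(frozen=True)
class QuadruplexHit:
    """A quadruplex-motif match: n_tracts G-tracts (C-tracts for minus strand)
    separated by 1..max_loop-base loops.  Plus-strand coordinates, half-open."""

    start: int
    end: int
    strand: Literal["+", "-"]
    n_tracts: int


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    """GC fraction over the unambiguous bases: (G + C) / (A + C + G + T).

    Ambiguity codes are excluded from both numerator and denominator.
    Raises ``ValueError`` if the sequence has no unambiguous base.
    """
    g = sequence.count("G")
    c = sequence.count("C")
    a = sequence.count("A")
    t = sequence.count("T")
    unambiguous = a + c + g + t
    if unambiguous == 0:
        raise ValueError("gc_fraction undefined: no unambiguous A/C/G/T base")
    return (g + c) / unambiguous


@lru_cache(maxsize=32)
def _stretch_pattern(k: int) -> re.Pattern[str]:
    return re.compile(f"[GC]{{{k},}}")


def find_gc_stretches(sequence: str, k: int = 3) -> list[StretchInterval]:
    """All maximal runs of >= k consecutive G or C bases, left to right.

    Any non-G/C character, including ambiguity codes, terminates a run.
    Returned intervals are sorted, non-overlapping and non-adjacent by
    construction (maximality separates them by at least one non-G/C base).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [
        StretchInterval(m.start(), m.end())
        for m in _stretch_pattern(k).finditer(sequence)
    ]


def compute_metrics(record: SeqRecordMeta, k: int = 3) -> CompositionMetrics:
    """Compute :class:`CompositionMetrics` for one sequence record.

    ``mean_stretch_len`` is the mean length of the maximal G/C runs of
    length >= k (``total_stretch_nt / n_stretches``), missing when there is
    no such run.
    """
    stretches = find_gc_stretches(record.sequence, k=k)
    lengths = [s.length for s in stretches]
    n = len(lengths)
    total = sum(lengths)
    return CompositionMetrics(
        id=record.id,
        gene=record.gene,
        species=record.species,
        group=record.group,
        length_nt=record.length,
        gc_fraction=gc_fraction(record.sequence),
        n_stretches=n,
        mean_stretch_len=(total / n) if n else None,
        max_stretch_len=max(lengths) if n else 0,
        total_stretch_nt=total,
    )


def _tract_chains(
    sequence: str, base: str, tract_len: int, max_loop: int, n_tracts: int
) -> list[tuple[int, int, int]]:
    """Left-greedy non-overlapping chains of >= n_tracts maximal ``base``-runs
    (each >= tract_len) with inter-run gaps of 1..max_loop bases.

    Returns (start, end, tract_count) triples in plus-strand coordinates.
    """
    runs = [
        (m.start(), m.end())
        for m in re.finditer(f"{base}{{{tract_len},}}", sequence)
    ]
    chains: list[tuple[int, int, int]] = []
    i = 0
    while i + n_tracts <= len(runs):
        j = i
        while (
            j + 1 < len(runs)
            and 1 <= runs[j + 1][0] - runs[j][1] <= max_loop
        ):
            j += 1
        count = j - i + 1
        if count >= n_tracts:
            chains.append((runs[i][0], runs[j][1], count))
            i = j + 1
        else:
            i += 1
    return chains


def scan_quadruplex(
    sequence: str,
    tract_len: int = 3,
    max_loop: int = 7,
    n_tracts: int = 4,
) -> list[QuadruplexHit]:
    """Scan both strands for quadruplex-forming motifs.

    A plus-strand hit is a chain of >= ``n_tracts`` maximal G-runs of length
    >= ``tract_len`` whose gaps (loops) span 1..``max_loop`` arbitrary
    bases; chains are assembled left-greedily and never overlap on a strand.
    Minus-strand hits apply the same rule to C-runs and are reported in
    plus-strand coordinates.  This is the canonical pattern-matching
    convention for quadruplex prediction, not a thermodynamic model.
    """
    if tract_len < 2:
        raise ValueError(f"tract_len must be >= 2, got {tract_len}")
    if max_loop < 1:
        raise ValueError(f"max_loop must be >= 1, got {max_loop}")
    if n_tracts < 2:
        raise ValueError(f"n_tracts must be >= 2, got {n_tracts}")
    hits = [
        QuadruplexHit(start, end, "+", count)
        for start, end, count in _tract_chains(
            sequence, "G", tract_len, max_loop, n_tracts
        )
    ]
    hits += [
        QuadruplexHit(start, end, "-", count)
        for start, end, count in _tract_chains(
            sequence, "C", tract_len, max_loop, n_tracts
        )
    ]
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def quadruplex_bed_rows(
    record_id: str, hits: list[QuadruplexHit]
) -> list[str]:
    """Render hits as BED6 rows (chrom, start, end, name, score=n_tracts, strand)."""
    return [
        f"{record_id}\t{h.start}\t{h.end}\t"
        f"{record_id}_G4_{i + 1}\t{h.n_tracts}\t{h.strand}"
        for i, h in enumerate(hits)
    ]
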