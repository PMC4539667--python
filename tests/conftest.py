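"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gcscreen.composition import CompositionMetrics
from gcscreen.seqio import SeqRecordMeta

_COMP = str.maketrans("ACGT", "TGCA")


def simple_revcomp(seq: str) -> str:
    """Independent reverse complement for the plain DNA alphabet."""
    return seq.translate(_COMP)[::-1]


def brute_force_stretches(seq: str, k: int = 3) -> list[tuple[int, int]]:
    """Quadratic oracle: test every substring for being a maximal all-G/C run."""
    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + k, n + 1):
            if (
                all(c in "GC" for c in seq[i:j])
                and (i == 0 or seq[i - 1] not in "GC")
                and (j == n or seq[j] not in "GC")
            ):
                out.append((i, j))
    return out


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the given expected GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("AGCT"), size=length, p=p))


def mk_metrics(
    id: str,
    gc: float,
    stretch: float | None,
    group: str | None = None,
    gene: str | None = None,
    species: str | None = None,
) -> CompositionMetrics:
    """Hand-built metrics record for screen-level tests (labels + two axes)."""
    n = 0 if stretch is None else 10
    total = 0 if stretch is None else int(round(stretch * n))
    return CompositionMetrics(
        id=id,
        gene=gene,
        species=species,
        group=group,
        length_nt=1000,
        gc_fraction=gc,
        n_stretches=n,
        mean_stretch_len=stretch,
        max_stretch_len=0 if stretch is None else int(stretch) + 2,
        total_stretch_nt=total,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210901)


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "two.fa"
    path.write_text(">geneA\nACGTACGT\n>geneB\nGGGCCCAAA\nTTT\n")
    return path


@pytest.fixture
def records_by_length():
    def make(lengths):
        return [
            SeqRecordMeta(id=f"r{i}", sequence="A" * n)
            for i, n in enumerate(lengths)
        ]

    return make
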