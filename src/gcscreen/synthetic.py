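"""Synthetic CDS-like sequences and GC-biased coverage profiles.

Sequences are generated by a two-state renewal (Markov-chain) process that
alternates "strong" runs of G/C with "weak" runs of A/T.  Run lengths are
geometric; the strong-run mean ``m_s`` is set directly and the weak-run mean
is derived as ``m_w = m_s * (1 - gc) / gc``, which makes the stationary
fraction of strong bases

    m_s / (m_s + m_w) = gc

exactly the target GC.  The two free parameters therefore map one-to-one
onto the two axes of the composition screen: target GC content and G/C-run
structure.  Within a strong run G and C are equiprobable and independent;
likewise A and T within weak runs, so every statistic is strand-symmetric
by construction.

The coverage model is a deliberately simple demonstrator of GC-biased
sequencing dropout: expected depth decays exponentially in the window GC
excess over a reference GC, ``depth * exp(-beta * max(0, gc_w - gc_ref))``.
It asserts the phenomenon (GC-rich windows lose coverage), not any
instrument-calibrated functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import gc_fraction
from .errors import ParameterError
from .seqio import SeqRecordMeta

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)  # strong pair first


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-state run-length sequence generator.

    ``mean_strong_run`` is the expected G/C run length (geometric, support
    >= 1); it must exceed 1 so the derived weak-run mean is well defined for
    every target GC.  The same spec and seed always regenerate identical
    sequences; sequence ``i`` draws from an independent stream seeded with
    ``seed + i`` (offset by ``index_offset`` at generation time).
    """

    n_seqs: int
    length_nt: int
    target_gc: float
    mean_strong_run: float
    seed: int
    id_prefix: str = "seq"
    gene: str | None = None
    species: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_gc < 1.0:
            raise ParameterError(
                f"target_gc must be in (0, 1), got {self.target_gc}"
            )
        if self.mean_strong_run <= 1.0:
            raise ParameterError(
                f"mean_strong_run must be > 1, got {self.mean_strong_run}"
            )
        if self.length_nt < 1:
            raise ParameterError(f"length_nt must be >= 1, got {self.length_nt}")
        if self.n_seqs < 1:
            raise ParameterError(f"n_seqs must be >= 1, got {self.n_seqs}")

    @property
    def mean_weak_run(self) -> float:
        """Derived expected A/T run length: m_s * (1 - gc) / gc."""
        return self.mean_strong_run * (1.0 - self.target_gc) / self.target_gc


@dataclass(frozen=True)
class CoverageProfile:
    """Expected sequencing depth per fixed-width window of one sequence."""

    record_id: str
    window: int
    starts: np.ndarray  # 0-based window starts
    ends: np.ndarray  # exclusive; last window may be partial
    window_gc: np.ndarray
    expected_coverage: np.ndarray
    base_depth: float
    beta: float
    gc_ref: float


def _simulate_one(
    rng: np.random.Generator, length: int, p_strong: float, p_weak: float,
    start_strong: bool,
) -> str:
    """One sequence: alternating geometric runs, then i.i.d. letters per state."""
    mean_run = 0.5 * (1.0 / p_strong + 1.0 / p_weak)
    batch = max(16, int(length / mean_run) + 8)
    chunks: list[np.ndarray] = []
    total = 0
    while total < length:
        strong_runs = rng.geometric(p_strong, batch)
        weak_runs = rng.geometric(p_weak, batch)
        runs = np.empty(2 * batch, dtype=np.int64)
        if start_strong:
            runs[0::2] = strong_runs
            runs[1::2] = weak_runs
        else:
            runs[0::2] = weak_runs
            runs[1::2] = strong_runs
        chunks.append(runs)
        total += int(runs.sum())
        batch = max(16, int((length - total) / mean_run) + 8)
    runs = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    first_is_strong = np.arange(runs.size) % 2 == (0 if start_strong else 1)
    strong_mask = np.repeat(first_is_strong, runs)[:length]
    coin = rng.integers(0, 2, size=length)
    # codes: strong -> G/C (indices 0/1), weak -> A/T (indices 2/3)
    codes = _BASES[np.where(strong_mask, coin, coin + 2)]
    return codes.tobytes().decode("ascii")


def simulate_sequences(
    spec: SyntheticSpec, index_offset: int = 0
) -> list[SeqRecordMeta]:
    """Generate ``spec.n_seqs`` sequences under the two-state run model.

    Record ``i`` (zero-based) is named ``{id_prefix}{i+1}`` and uses its own
    generator seeded with ``spec.seed + index_offset + i``, so regeneration
    is independent of batch order and two specs sharing parameters but
    offset streams produce independent samples.
    """
    p_strong = 1.0 / spec.mean_strong_run
    p_weak = 1.0 / spec.mean_weak_run
    records = []
    for i in range(spec.n_seqs):
        rng = np.random.default_rng(spec.seed + index_offset + i)
        start_strong = bool(rng.random() < spec.target_gc)
        seq = _simulate_one(rng, spec.length_nt, p_strong, p_weak, start_strong)
        records.append(
            SeqRecordMeta(
                id=f"{spec.id_prefix}{i + 1}",
                sequence=seq,
                gene=spec.gene,
                species=spec.species,
                group=spec.group,
            )
        )
    return records


def simulate_panel(
    background_spec: SyntheticSpec,
    outlier_spec: SyntheticSpec,
    n_outliers: int,
) -> list[SeqRecordMeta]:
    """Background plus spike-in panel for end-to-end screening experiments.

    Background records come first, labeled ``group="background"`` with ids
    ``bg1..bgN``; outliers follow as ``group="outlier"``, ids ``out1..outM``.
    Outlier streams are offset past the background count so the two groups
    are independent even when the specs coincide (the null-calibration
    construction).
    """
    if n_outliers < 0:
        raise ParameterError(f"n_outliers must be >= 0, got {n_outliers}")
    from dataclasses import replace

    bg = simulate_sequences(
        replace(background_spec, id_prefix="bg", group="background")
    )
    out = simulate_sequences(
        replace(
            outlier_spec, n_seqs=n_outliers, id_prefix="out", group="outlier"
        ),
        index_offset=background_spec.n_seqs,
    ) if n_outliers else []
    return bg + out


def simulate_coverage(
    record: SeqRecordMeta,
    window: int = 50,
    base_depth: float = 30.0,
    beta: float = 0.0,
    gc_ref: float = 0.5,
) -> CoverageProfile:
    """Expected NGS coverage per window under the exponential GC-bias model.

    Windows tile the sequence at fixed width ``window`` (final partial
    window kept, scored with its own GC).  ``beta = 0`` gives uniform
    coverage at ``base_depth``; for ``beta > 0`` coverage decays as
    ``exp(-beta * (gc_w - gc_ref))`` once window GC exceeds ``gc_ref``.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if base_depth <= 0:
        raise ParameterError(f"base_depth must be > 0, got {base_depth}")
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    starts = np.arange(0, record.length, window)
    ends = np.minimum(starts + window, record.length)
    window_gc = np.array(
        [
            gc_fraction(record.sequence[s:e])
            for s, e in zip(starts, ends)
        ]
    )
    expected = base_depth * np.exp(-beta * np.maximum(0.0, window_gc - gc_ref))
    return CoverageProfile(
        record_id=record.id,
        window=window,
        starts=starts,
        ends=ends,
        window_gc=window_gc,
        expected_coverage=expected,
        base_depth=base_depth,
        beta=beta,
        gc_ref=gc_ref,
    )


def write_coverage_table(
    profiles: Sequence[CoverageProfile],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write coverage profiles as a bedgraph-style TSV
    (id, start, end, window_gc, expected_coverage)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("id\tstart\tend\twindow_gc\texpected_coverage\n")
        for p in profiles:
            for s, e, g, c in zip(
                p.starts, p.ends, p.window_gc, p.expected_coverage
            ):
                fh.write(f"{p.record_id}\t{s}\t{e}\t{g:.6f}\t{c:.6f}\n")
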