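"""Reading and writing of sequence sets and tabular results.

Input coding sequences arrive as multi-record FASTA (wrapped or unwrapped),
optionally with a sidecar tab-separated metadata table mapping record IDs to
gene symbol, species and group label.  Sequences are normalized on load:
uppercased, RNA ``U`` mapped to ``T``, and validated against the IUPAC
nucleotide alphabet.  All tabular outputs are TSV with a header row, UTF-8,
LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DuplicateIdError, FastaParseError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (after U -> T normalization).
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

#: Column order of the per-sequence metrics table.
METRICS_COLUMNS = [
    "id",
    "gene",
    "species",
    "group",
    "length_nt",
    "gc_fraction",
    "n_stretches",
    "mean_stretch_len",
    "max_stretch_len",
    "total_stretch_nt",
]

_METADATA_COLUMNS = ["id", "gene", "species", "group"]


@dataclass(frozen=True)
class SeqRecordMeta:
    """A nucleotide sequence with identity and optional gene/species/group labels.

    The sequence is stored normalized (uppercase, DNA alphabet); ``length``
    is always ``len(sequence)``.
    """

    id: str
    sequence: str
    gene: str | None = None
    species: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, map U to T, and validate against the IUPAC nucleotide codes."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise FastaParseError(
            f"record {record_id!r}: invalid nucleotide code(s) "
            + ", ".join(sorted(bad))
        )
    return seq


def _read_metadata(path: str | Path) -> dict[str, dict[str, str | None]]:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"metadata table {path} lacks required column(s): {', '.join(missing)}"
        )
    meta: dict[str, dict[str, str | None]] = {}
    for row in table.itertuples(index=False):
        labels = {
            col: (getattr(row, col) if pd.notna(getattr(row, col)) else None)
            for col in ("gene", "species", "group")
        }
        meta[str(row.id)] = labels
    return meta


def read_fasta(
    path: str | Path, metadata: str | Path | None = None
) -> list[SeqRecordMeta]:
    """Load a FASTA file into :class:`SeqRecordMeta` records.

    Sequences are normalized (uppercase, U->T).  If ``metadata`` is given it
    must be a TSV with columns ``id, gene, species, group``; labels are
    joined on exact id match.  Records absent from the table keep empty
    labels; table ids absent from the FASTA produce a warning, not an error.

    Raises
    ------
    FastaParseError
        Malformed FASTA (leading non-header text, empty sequence, invalid
        characters); the message names the offending record.
    DuplicateIdError
        The same record id appears more than once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text_head = path.read_text(encoding="utf-8")[:4096].lstrip()
    if text_head and not text_head.startswith(">"):
        raise FastaParseError(
            f"{path}: not a FASTA file (first non-blank character is not '>')"
        )

    records: list[SeqRecordMeta] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"record {rec.id!r}: empty sequence")
        records.append(SeqRecordMeta(id=rec.id, sequence=normalize_sequence(seq, rec.id)))
        seen[rec.id] = seen.get(rec.id, 0) + 1

    duplicates = [rid for rid, n in seen.items() if n > 1]
    if duplicates:
        raise DuplicateIdError(duplicates)

    if metadata is not None:
        meta = _read_metadata(metadata)
        fasta_ids = set(seen)
        orphans = sorted(set(meta) - fasta_ids)
        if orphans:
            logger.warning(
                "%d metadata id(s) not present in FASTA: %s",
                len(orphans),
                ", ".join(orphans[:10]) + ("..." if len(orphans) > 10 else ""),
            )
        records = [
            replace(r, **meta[r.id]) if r.id in meta else r for r in records
        ]
    return records


def filter_min_length(
    records: Sequence[SeqRecordMeta], min_len: int = 300
) -> list[SeqRecordMeta]:
    """Keep records with ``length >= min_len`` (default 300 nt), preserving order.

    The default implements the convention that only coding sequences longer
    than 299 nt enter the composition analysis.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return [r for r in records if r.length >= min_len]


def write_fasta(
    records: Iterable[SeqRecordMeta], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA (LF line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_metadata_table(
    records: Iterable[SeqRecordMeta],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the id/gene/species/group sidecar TSV for a record set."""
    table = pd.DataFrame(
        [
            {"id": r.id, "gene": r.gene, "species": r.species, "group": r.group}
            for r in records
        ],
        columns=_METADATA_COLUMNS,
    )
    _write_tsv(table, path, header_lines, float_format=None)


def write_metrics_table(
    metrics: Sequence,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write per-sequence composition metrics as TSV.

    Columns: ``id, gene, species, group, length_nt, gc_fraction, n_stretches,
    mean_stretch_len, max_stretch_len, total_stretch_nt``.  Floats carry six
    decimal places; a missing mean stretch length is written as ``NA``; row
    order equals input order.  ``header_lines`` are prepended verbatim
    (callers use them for ``#``-comment provenance headers).
    """
    table = pd.DataFrame(
        [
            {
                "id": m.id,
                "gene": m.gene,
                "species": m.species,
                "group": m.group,
                "length_nt": m.length_nt,
                "gc_fraction": m.gc_fraction,
                "n_stretches": m.n_stretches,
                "mean_stretch_len": m.mean_stretch_len,
                "max_stretch_len": m.max_stretch_len,
                "total_stretch_nt": m.total_stretch_nt,
            }
            for m in metrics
        ],
        columns=METRICS_COLUMNS,
    )
    _write_tsv(table, path, header_lines, float_format="%.6f")


def read_metrics_table(path: str | Path) -> list:
    """Read a metrics TSV (as written by :func:`write_metrics_table`) back
    into :class:`~gcscreen.composition.CompositionMetrics` records.

    ``#``-prefixed header lines are skipped; ``NA`` maps to ``None``.
    """
    from .composition import CompositionMetrics  # deferred: avoids module cycle

    table = pd.read_csv(
        path, sep="\t", comment="#", dtype={"id": str}, na_values=["NA"]
    )
    missing = [c for c in METRICS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"metrics table {path} lacks column(s): {', '.join(missing)}"
        )

    def _opt(v):
        return None if pd.isna(v) else v

    out = []
    for row in table.itertuples(index=False):
        out.append(
            CompositionMetrics(
                id=str(row.id),
                gene=_opt(row.gene),
                species=_opt(row.species),
                group=_opt(row.group),
                length_nt=int(row.length_nt),
                gc_fraction=float(row.gc_fraction),
                n_stretches=int(row.n_stretches),
                mean_stretch_len=(
                    None if pd.isna(row.mean_stretch_len) else float(row.mean_stretch_len)
                ),
                max_stretch_len=int(row.max_stretch_len),
                total_stretch_nt=int(row.total_stretch_nt),
            )
        )
    return out


def _write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str],
    float_format: str | None,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        table.to_csv(
            fh,
            sep="\t",
            index=False,
            na_rep="NA",
            float_format=float_format,
            lineterminator="\n",
        )
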