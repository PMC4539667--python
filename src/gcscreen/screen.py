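"""Background distributions, outlier calls and group comparisons.

A background model is the empirical distribution of GC fraction and mean
G/C-stretch length over a reference gene set (in the motivating analysis,
~6,000 chicken RefSeq coding sequences).  Query genes are scored by their
percentile rank in that background and flagged as compositional outliers
when they exceed configurable percentile thresholds on one or both axes.

Group-to-group distribution comparison uses the maximum absolute difference
between the two empirical CDFs (the two-sample Kolmogorov-Smirnov statistic)
with a label-permutation null, so the p-value relies only on
exchangeability, not on any distributional assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionMetrics
from .errors import InsufficientBackgroundError, UnknownGroupError

logger = logging.getLogger(__name__)

MetricName = Literal["gc_fraction", "mean_stretch_len"]

_METRIC_NAMES = ("gc_fraction", "mean_stretch_len")


@dataclass(frozen=True)
class BackgroundModel:
    """Empirical reference distribution of composition metrics.

    ``gc_values`` covers every reference record; ``stretch_values`` excludes
    records with a missing mean stretch length (no run >= k), whose count is
    kept in ``n_missing_stretch``.
    """

    n: int
    gc_values: np.ndarray  # sorted
    stretch_values: np.ndarray  # sorted, missing excluded
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_missing_stretch: int
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OutlierCall:
    """Outlier decision for one query, with the thresholds that produced it."""

    id: str
    gc_percentile: float
    stretch_percentile: float | None
    flagged: bool
    rule: str
    caveat: str | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample ECDF comparison with a permutation p-value.

    ``D`` is the exact maximum absolute ECDF difference over the pooled
    support; ``p_perm = (1 + #{D* >= D}) / (1 + n_perm)``.
    """

    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    D: float
    p_perm: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class OrthologContrast:
    """Per-group composition summary for one gene across clade groups."""

    gene: str
    summary: pd.DataFrame
    comparisons: list[GroupComparison]
    skipped: list[tuple[str, str, str]]  # (group_a, group_b, reason)


def build_background(
    metrics: Sequence[CompositionMetrics],
    min_n: int = 100,
    bin_width: float = 0.1,
    hist_start: float = 3.0,
    provenance: dict | None = None,
) -> BackgroundModel:
    """Build the empirical background distribution from reference metrics.

    Records with a missing mean stretch length are excluded from the stretch
    axis (their count is logged and stored); at least ``min_n`` usable
    records are required.  The stretch histogram uses fixed-width bins of
    ``bin_width`` starting at ``hist_start`` (the run-length threshold k,
    the smallest possible mean).
    """
    if min_n < 1:
        raise ValueError(f"min_n must be >= 1, got {min_n}")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    stretch = np.sort(
        [m.mean_stretch_len for m in metrics if m.mean_stretch_len is not None]
    )
    n_missing = len(metrics) - len(stretch)
    if len(stretch) < min_n:
        raise InsufficientBackgroundError(len(stretch), min_n, len(metrics))
    if n_missing:
        logger.info(
            "background: %d of %d records have no G/C stretch and are "
            "excluded from the stretch axis",
            n_missing,
            len(metrics),
        )
    gc = np.sort([m.gc_fraction for m in metrics])
    n_bins = max(1, int(np.ceil((stretch[-1] - hist_start) / bin_width)))
    edges = hist_start + bin_width * np.arange(n_bins + 1)
    if edges[-1] < stretch[-1]:  # guard against float rounding at the top edge
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(stretch, bins=edges)
    return BackgroundModel(
        n=len(metrics),
        gc_values=gc,
        stretch_values=stretch,
        hist_edges=edges,
        hist_counts=counts,
        n_missing_stretch=n_missing,
        provenance=dict(provenance or {}),
    )


def percentile_rank(model: BackgroundModel, metric: MetricName, q: float) -> float:
    """Inclusive percentile rank of ``q``: ``100 * #{x <= q} / n``.

    Values above the background maximum return 100; below the minimum, 0.
    """
    if metric == "gc_fraction":
        values = model.gc_values
    elif metric == "mean_stretch_len":
        values = model.stretch_values
    else:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {_METRIC_NAMES}"
        )
    return 100.0 * float(np.searchsorted(values, q, side="right")) / len(values)


def flag_outliers(
    queries: Sequence[CompositionMetrics],
    model: BackgroundModel,
    gc_pct: float = 99.0,
    stretch_pct: float = 99.0,
    mode: Literal["both", "either"] = "both",
) -> list[OutlierCall]:
    """Score queries against the background and flag compositional outliers.

    A query is flagged when its percentile ranks meet the thresholds on both
    axes (``mode="both"``, the default) or on at least one (``"either"``).
    Queries with a missing mean stretch length can never pass the stretch
    axis and carry a caveat in the call.
    """
    for name, value in (("gc_pct", gc_pct), ("stretch_pct", stretch_pct)):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {value}")
    if mode not in ("both", "either"):
        raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")
    rule = (
        f"gc_percentile>={gc_pct:g} "
        f"{'AND' if mode == 'both' else 'OR'} "
        f"stretch_percentile>={stretch_pct:g}"
    )
    calls: list[OutlierCall] = []
    for q in queries:
        gc_rank = percentile_rank(model, "gc_fraction", q.gc_fraction)
        gc_pass = gc_rank >= gc_pct
        if q.mean_stretch_len is None:
            stretch_rank = None
            stretch_pass = False
            caveat = "no G/C stretch >= k; stretch axis undefined, never flagged on it"
        else:
            stretch_rank = percentile_rank(
                model, "mean_stretch_len", q.mean_stretch_len
            )
            stretch_pass = stretch_rank >= stretch_pct
            caveat = None
        flagged = (
            (gc_pass and stretch_pass) if mode == "both" else (gc_pass or stretch_pass)
        )
        calls.append(
            OutlierCall(
                id=q.id,
                gc_percentile=gc_rank,
                stretch_percentile=stretch_rank,
                flagged=flagged,
                rule=rule,
                caveat=caveat,
            )
        )
    return calls


def _ecdf_max_distance_int(
    labels_a: np.ndarray, order: np.ndarray, eval_mask: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """Scaled KS distance ``D * n_a * n_b`` as exact integers.

    ``labels_a`` is an (n_perm, n) 0/1 matrix (1 = group a) in pooled input
    order; ``order`` sorts the pooled values; ``eval_mask`` marks the last
    occurrence of each distinct pooled value, where the ECDF difference is
    evaluated (tied values contribute a single evaluation point).
    """
    ordered = labels_a[:, order]
    cum_a = np.cumsum(ordered, axis=1)
    ranks = np.arange(1, ordered.shape[1] + 1)
    diffs = np.abs(cum_a * n_b - (ranks - cum_a) * n_a)
    return diffs[:, eval_mask].max(axis=1)


def ecdf_max_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sample KS statistic sup |ECDF_a - ECDF_b| over pooled support."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    svals = pooled[order]
    eval_mask = np.r_[svals[1:] != svals[:-1], True]
    labels = np.zeros((1, len(pooled)), dtype=np.int64)
    labels[0, : len(a)] = 1
    d_int = _ecdf_max_distance_int(labels, order, eval_mask, len(a), len(b))[0]
    return float(d_int) / (len(a) * len(b))


def _metric_values(
    metrics: Iterable[CompositionMetrics], metric: str
) -> dict[str, list[float]]:
    if metric not in _METRIC_NAMES:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {_METRIC_NAMES}"
        )
    by_group: dict[str, list[float]] = {}
    for m in metrics:
        if m.group is None:
            continue
        value = getattr(m, metric)
        if value is None:
            continue
        by_group.setdefault(m.group, []).append(float(value))
    return by_group


def compare_groups(
    metrics: Sequence[CompositionMetrics],
    group_a: str,
    group_b: str,
    metric: MetricName = "gc_fraction",
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Permutation two-sample test on one metric between two labeled groups.

    The statistic is the exact maximum ECDF difference D; the null is built
    by permuting group labels ``n_perm`` times with a seeded generator, and
    ``p_perm = (1 + #{D* >= D}) / (1 + n_perm)``.  D and every permuted D*
    are compared in exact integer arithmetic, so ties are handled without
    floating-point hazards and runs are bit-reproducible for a given seed.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    by_group = _metric_values(metrics, metric)
    for label in (group_a, group_b):
        if label not in by_group:
            raise UnknownGroupError(label, by_group)
    a = np.asarray(by_group[group_a], dtype=float)
    b = np.asarray(by_group[group_b], dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError(
            f"both groups need >= 5 non-missing values; "
            f"got {group_a}: {len(a)}, {group_b}: {len(b)}"
        )
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    svals = pooled[order]
    eval_mask = np.r_[svals[1:] != svals[:-1], True]

    base = np.zeros(n_a + n_b, dtype=np.int64)
    base[:n_a] = 1
    obs_int = _ecdf_max_distance_int(
        base[None, :], order, eval_mask, n_a, n_b
    )[0]

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    null_int = _ecdf_max_distance_int(perms, order, eval_mask, n_a, n_b)

    p = (1 + int(np.count_nonzero(null_int >= obs_int))) / (1 + n_perm)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        n_a=n_a,
        n_b=n_b,
        D=float(obs_int) / (n_a * n_b),
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
    )


def ortholog_contrast(
    metrics: Sequence[CompositionMetrics],
    gene: str,
    clade_groups: dict[str, Iterable[str]] | None = None,
    min_compare_n: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> OrthologContrast:
    """Summarize one gene's composition per clade group, with pairwise tests.

    ``clade_groups`` optionally partitions species into named groups (e.g.
    ``{"birds": [...], "mammals": [...]}``); records whose species is not in
    the partition are dropped.  Without it, each record's own group label is
    used.  For every group pair where both sides have at least
    ``min_compare_n`` values, a :func:`compare_groups` result on GC fraction
    is included; smaller pairs are listed as skipped with the reason.
    """
    selected = [m for m in metrics if m.gene == gene]
    if not selected:
        available = sorted({m.gene for m in metrics if m.gene})
        raise ValueError(
            f"gene {gene!r} absent from metrics; available genes: "
            + (", ".join(available) or "(none)")
        )
    if clade_groups is not None:
        species_to_group = {
            sp: grp for grp, members in clade_groups.items() for sp in members
        }
        from dataclasses import replace

        selected = [
            replace(m, group=species_to_group[m.species])
            for m in selected
            if m.species in species_to_group
        ]
    selected = [m for m in selected if m.group is not None]
    groups = sorted({m.group for m in selected})
    if not groups:
        raise ValueError(f"gene {gene!r}: no record carries a group label")

    rows = []
    for grp in groups:
        sub = [m for m in selected if m.group == grp]
        gc = [m.gc_fraction for m in sub]
        st = [m.mean_stretch_len for m in sub if m.mean_stretch_len is not None]
        rows.append(
            {
                "group": grp,
                "n": len(sub),
                "gc_mean": float(np.mean(gc)),
                "gc_min": float(np.min(gc)),
                "gc_max": float(np.max(gc)),
                "stretch_mean": float(np.mean(st)) if st else np.nan,
                "stretch_min": float(np.min(st)) if st else np.nan,
                "stretch_max": float(np.max(st)) if st else np.nan,
            }
        )
    summary = pd.DataFrame(rows)

    comparisons: list[GroupComparison] = []
    skipped: list[tuple[str, str, str]] = []
    counts = {grp: sum(1 for m in selected if m.group == grp) for grp in groups}
    for ga, gb in combinations(groups, 2):
        if counts[ga] >= min_compare_n and counts[gb] >= min_compare_n:
            comparisons.append(
                compare_groups(
                    selected, ga, gb, metric="gc_fraction", n_perm=n_perm, seed=seed
                )
            )
        else:
            skipped.append(
                (
                    ga,
                    gb,
                    f"needs n >= {min_compare_n} per group, got "
                    f"{counts[ga]} and {counts[gb]}",
                )
            )
    return OrthologContrast(
        gene=gene, summary=summary, comparisons=comparisons, skipped=skipped
    )


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons for TSV export."""
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "metric": c.metric,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "D": c.D,
                "p_perm": c.p_perm,
                "n_perm": c.n_perm,
                "seed": c.seed,
            }
            for c in comparisons
        ],
        columns=[
            "group_a",
            "group_b",
            "metric",
            "n_a",
            "n_b",
            "D",
            "p_perm",
            "n_perm",
            "seed",
        ],
    )
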