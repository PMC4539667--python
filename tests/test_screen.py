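"""Background model, percentile ranks, outlier flagging, and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcscreen.errors import InsufficientBackgroundError, UnknownGroupError
from gcscreen.screen import (
    build_background,
    compare_groups,
    ecdf_max_distance,
    flag_outliers,
    ortholog_contrast,
    percentile_rank,
)
from tests.conftest import mk_metrics


def background_of(values):
    """Background whose stretch axis mirrors gc axis, for counting tests."""
    return build_background(
        [mk_metrics(f"b{i}", v / 100.0, 3.0 + v / 10.0) for i, v in enumerate(values)],
        min_n=len(values),
    )


class TestBackground:
    def test_count_contract(self):
        model = background_of(range(1, 201))
        assert model.n == 200
        assert len(model.gc_values) == 200
        assert model.hist_counts.sum() == 200

    def test_insufficient_background(self):
        metrics = [mk_metrics(f"b{i}", 0.5, 4.0) for i in range(50)]
        with pytest.raises(InsufficientBackgroundError, match="50"):
            build_background(metrics, min_n=100)

    def test_missing_stretch_excluded_and_counted(self):
        metrics = [mk_metrics(f"b{i}", 0.5, 4.0) for i in range(100)]
        metrics += [mk_metrics("nostretch", 0.1, None)]
        model = build_background(metrics, min_n=100)
        assert model.n == 101
        assert len(model.stretch_values) == 100
        assert model.n_missing_stretch == 1

    def test_histogram_spans_data(self):
        model = background_of(range(1, 151))
        assert model.hist_edges[0] == pytest.approx(3.0)
        assert model.hist_edges[-1] >= model.stretch_values[-1]
        widths = np.diff(model.hist_edges)
        assert np.allclose(widths, 0.1)


class TestPercentileRank:
    def test_counting_example_1_to_100(self):
        model = background_of(range(1, 101))
        # gc values are 0.01 .. 1.00
        assert percentile_rank(model, "gc_fraction", 1.00) == 100.0
        assert percentile_rank(model, "gc_fraction", 0.01) == 1.0
        assert percentile_rank(model, "gc_fraction", 0.005) == 0.0
        assert percentile_rank(model, "gc_fraction", 2.0) == 100.0

    def test_unknown_metric(self):
        model = background_of(range(1, 101))
        with pytest.raises(ValueError, match="unknown metric"):
            percentile_rank(model, "codon_bias", 0.5)

    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=5,
            max_size=60,
        ),
        q=st.floats(min_value=-0.5, max_value=1.5, allow_nan=False),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_counting_oracle(self, values, q):
        model = build_background(
            [mk_metrics(f"b{i}", v, 4.0) for i, v in enumerate(values)],
            min_n=len(values),
        )
        expected = 100.0 * sum(v <= q for v in values) / len(values)
        assert percentile_rank(model, "gc_fraction", q) == pytest.approx(expected)


class TestFlagOutliers:
    @pytest.fixture
    def model(self):
        return background_of(range(1, 101))

    def test_beyond_background_max_flagged_both(self, model):
        (call,) = flag_outliers([mk_metrics("q", 2.0, 50.0)], model)
        assert call.flagged
        assert call.gc_percentile == 100.0
        assert call.stretch_percentile == 100.0

    def test_median_query_not_flagged(self, model):
        (call,) = flag_outliers([mk_metrics("q", 0.50, 8.0)], model)
        assert not call.flagged

    def test_threshold_zero_either_flags_everything(self, model):
        calls = flag_outliers(
            [mk_metrics("lo", -1.0, 0.1), mk_metrics("hi", 2.0, 99.0)],
            model,
            gc_pct=0.0,
            stretch_pct=0.0,
            mode="either",
        )
        assert all(c.flagged for c in calls)

    def test_threshold_100_flags_only_at_or_above_max(self, model):
        calls = flag_outliers(
            [mk_metrics("max", 1.00, 13.0), mk_metrics("near", 0.999, 12.99)],
            model,
            gc_pct=100.0,
            stretch_pct=100.0,
        )
        assert [c.flagged for c in calls] == [True, False]

    def test_missing_stretch_never_flagged_on_stretch(self, model):
        (call,) = flag_outliers(
            [mk_metrics("q", 2.0, None)], model, mode="both"
        )
        assert call.stretch_percentile is None
        assert not call.flagged
        assert call.caveat is not None
        (either,) = flag_outliers(
            [mk_metrics("q", 2.0, None)], model, mode="either"
        )
        assert either.flagged  # gc axis alone can still flag in either mode

    def test_rule_recorded(self, model):
        (call,) = flag_outliers([mk_metrics("q", 0.5, 8.0)], model,
                                gc_pct=95, stretch_pct=90, mode="either")
        assert "95" in call.rule and "90" in call.rule and "OR" in call.rule

    def test_empty_queries(self, model):
        assert flag_outliers([], model) == []

    def test_bad_threshold(self, model):
        with pytest.raises(ValueError):
            flag_outliers([], model, gc_pct=101)


def groups_from(a_values, b_values, metric="gc_fraction"):
    out = []
    for i, v in enumerate(a_values):
        out.append(
            mk_metrics(f"a{i}", v, v + 3.0, group="a")
            if metric == "gc_fraction"
            else mk_metrics(f"a{i}", 0.5, v, group="a")
        )
    for i, v in enumerate(b_values):
        out.append(
            mk_metrics(f"b{i}", v, v + 3.0, group="b")
            if metric == "gc_fraction"
            else mk_metrics(f"b{i}", 0.5, v, group="b")
        )
    return out


class TestCompareGroups:
    def test_identical_samples(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = compare_groups(groups_from(vals, vals), "a", "b", seed=1, n_perm=99)
        assert res.D == 0.0
        assert res.p_perm == 1.0

    def test_disjoint_supports(self):
        res = compare_groups(
            groups_from([0.1, 0.12, 0.2, 0.25, 0.3], [0.7, 0.75, 0.8, 0.85, 0.9]),
            "a", "b", seed=1, n_perm=199,
        )
        assert res.D == 1.0
        # only 2 of the C(10,5) label splits reach D = 1, so p is small
        assert res.p_perm <= 0.05

    def test_small_sample_exact_D(self):
        # {1,2,3,4} vs {2,3,4,5}: ECDFs differ by 1/4 at every pooled point
        d = ecdf_max_distance([1, 2, 3, 4], [2, 3, 4, 5])
        assert d == pytest.approx(0.25)

    def test_unknown_group_lists_available(self):
        metrics = groups_from([0.1] * 5, [0.2] * 5)
        with pytest.raises(UnknownGroupError, match="a, b"):
            compare_groups(metrics, "a", "c", seed=0, n_perm=99)

    def test_min_group_size_enforced(self):
        metrics = groups_from([0.1] * 4, [0.2] * 5)
        with pytest.raises(ValueError, match=">= 5"):
            compare_groups(metrics, "a", "b", seed=0, n_perm=99)

    def test_min_n_perm_enforced(self):
        metrics = groups_from([0.1] * 5, [0.2] * 5)
        with pytest.raises(ValueError, match="n_perm"):
            compare_groups(metrics, "a", "b", seed=0, n_perm=50)

    def test_seed_reproducibility(self, rng):
        a = list(rng.normal(0.5, 0.05, 30))
        b = list(rng.normal(0.52, 0.05, 30))
        r1 = compare_groups(groups_from(a, b), "a", "b", seed=7, n_perm=500)
        r2 = compare_groups(groups_from(a, b), "a", "b", seed=7, n_perm=500)
        assert (r1.D, r1.p_perm) == (r2.D, r2.p_perm)

    def test_D_matches_scipy_ks(self, rng):
        # independent cross-check of the statistic on random samples
        from scipy.stats import ks_2samp

        for _ in range(20):
            a = rng.normal(0.0, 1.0, int(rng.integers(5, 40)))
            b = rng.normal(0.3, 1.2, int(rng.integers(5, 40)))
            assert ecdf_max_distance(a, b) == pytest.approx(
                ks_2samp(a, b).statistic
            )

    def test_D_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(0.1, 0.9, 25)
        b = rng.uniform(0.2, 1.0, 25)
        d0 = ecdf_max_distance(a, b)
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            assert ecdf_max_distance(f(a), f(b)) == pytest.approx(d0)

    def test_stretch_metric_skips_missing(self):
        metrics = groups_from([4.0, 4.1, 4.2, 4.3, 4.4],
                              [5.0, 5.1, 5.2, 5.3, 5.4],
                              metric="mean_stretch_len")
        metrics.append(mk_metrics("amiss", 0.5, None, group="a"))
        res = compare_groups(metrics, "a", "b", metric="mean_stretch_len",
                             seed=0, n_perm=99)
        assert res.n_a == 5  # the missing-stretch record is not a sample point


class TestOrthologContrast:
    def _panel(self):
        metrics = []
        for i in range(6):
            metrics.append(
                mk_metrics(f"av{i}", 0.72 + 0.005 * i, 6.0 + 0.1 * i,
                           gene="EPO", species=f"bird{i}", group="birds")
            )
            metrics.append(
                mk_metrics(f"mam{i}", 0.55 + 0.005 * i, 4.5 + 0.1 * i,
                           gene="EPO", species=f"mammal{i}", group="mammals")
            )
        metrics.append(mk_metrics("other", 0.5, 4.0, gene="LPPR2",
                                  species="bird0", group="birds"))
        return metrics

    def test_group_means_ordered(self):
        res = ortholog_contrast(self._panel(), "EPO", n_perm=99, seed=3)
        summary = res.summary.set_index("group")
        assert summary.loc["birds", "gc_mean"] > summary.loc["mammals", "gc_mean"]
        assert len(res.comparisons) == 1
        assert res.comparisons[0].D == 1.0  # fully separated GC distributions

    def test_single_group_no_comparisons(self):
        metrics = [mk_metrics("x", 0.7, 6.0, gene="EPO", species="s", group="birds")]
        res = ortholog_contrast(metrics, "EPO", n_perm=99)
        assert len(res.summary) == 1
        assert res.comparisons == [] and res.skipped == []

    def test_small_groups_skipped_with_reason(self):
        metrics = [
            mk_metrics(f"a{i}", 0.7, 6.0, gene="EPO", species=f"s{i}", group="g1")
            for i in range(3)
        ] + [
            mk_metrics(f"b{i}", 0.5, 4.0, gene="EPO", species=f"t{i}", group="g2")
            for i in range(3)
        ]
        res = ortholog_contrast(metrics, "EPO", n_perm=99)
        assert len(res.summary) == 2
        assert res.comparisons == []
        assert len(res.skipped) == 1 and "n >= 5" in res.skipped[0][2]

    def test_clade_partition_overrides_labels(self):
        res = ortholog_contrast(
            self._panel(),
            "EPO",
            clade_groups={"avian": [f"bird{i}" for i in range(6)],
                          "non-avian": [f"mammal{i}" for i in range(6)]},
            n_perm=99,
        )
        assert sorted(res.summary["group"]) == ["avian", "non-avian"]

    def test_absent_gene_error(self):
        with pytest.raises(ValueError, match="EPOR"):
            ortholog_contrast(self._panel(), "EPOR", n_perm=99)
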