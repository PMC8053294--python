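"""Impact/flux scoring: worked arithmetic, invariants, ranking rules."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diaflux import (
    DEGTable,
    GeneSet,
    GeneSetCollection,
    GeneStat,
    PathwayHierarchy,
    ValidationError,
    aggregate_hierarchy,
    compute_impact,
    count_by_direction,
    rank_top,
    score_collection,
    select_deg,
)
from diaflux.model import HierarchyEntry, ImpactResult


def make_table(rows):
    """rows: (gene_id, log2fc, pvalue, fdr)"""
    return DEGTable([GeneStat(*r) for r in rows])


def naive_impact(members, table, cutoff=0.10):
    """Independent re-implementation of the scoring formula, straight from
    its definition, for cross-checking."""
    background = [g for g in members if g in table]
    deg = [g for g in background if table[g].fdr <= cutoff]
    if not background or not deg:
        return 0.0, 0.0
    pi = len(deg) / len(background)
    m = sum(abs(table[g].log2fc) for g in deg) / len(deg)
    s = sum(-math.log10(table[g].pvalue) for g in deg) / len(deg)
    impact = 100 * pi * m * s
    denom = sum(abs(table[g].log2fc) for g in deg)
    d = sum(table[g].log2fc for g in deg) / denom if denom else 0.0
    return impact, impact * d


class TestSelectDeg:
    def test_filter_and_inclusive_boundary(self):
        table = make_table(
            [("a", 1, 0.01, 0.04), ("b", 1, 0.02, 0.09), ("c", 1, 0.1, 0.20)]
        )
        assert select_deg(table, 0.10) == {"a", "b"}
        boundary = make_table([("a", 1, 0.05, 0.10)])
        assert select_deg(boundary, 0.10) == {"a"}

    def test_invalid_cutoff_rejected(self):
        table = make_table([("a", 1, 0.01, 0.04)])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                select_deg(table, bad)

    def test_deterministic_on_seeded_cohort(self, default_bundle):
        first = select_deg(default_bundle.table, 0.05)
        second = select_deg(default_bundle.table, 0.05)
        assert first == second and len(first) > 0


class TestCountByDirection:
    def test_up_down_split(self):
        table = make_table([("a", 2, 0.01, 0.02), ("b", -1, 0.01, 0.02)])
        counts = count_by_direction({"a", "b"}, table)
        assert (counts.n_up, counts.n_down, counts.n_zero) == (1, 1, 0)

    def test_zero_fold_change_counted_separately(self):
        table = make_table([("a", 0.0, 0.5, 0.9)])
        counts = count_by_direction({"a"}, table)
        assert tuple(counts) == (0, 0) and counts.n_zero == 1

    def test_hand_tally_ten_genes(self):
        rows = [(f"g{i}", (-1) ** i * (0.1 * i), 0.01, 0.02) for i in range(10)]
        table = make_table(rows)
        counts = count_by_direction({f"g{i}" for i in range(10)}, table)
        # i=0 gives log2fc 0; even i>0 positive, odd negative
        assert (counts.n_up, counts.n_down, counts.n_zero) == (4, 5, 1)

    def test_unknown_gene_errors(self):
        table = make_table([("a", 1, 0.01, 0.02)])
        with pytest.raises(ValidationError):
            count_by_direction({"zz"}, table)


class TestComputeImpact:
    def test_worked_example(self, fixture_bundle):
        res = compute_impact(fixture_bundle.sets["S_A"], fixture_bundle.table, 0.10)
        assert res.n_background == 5 and res.n_deg == 2
        assert res.proportion == pytest.approx(0.4)
        assert res.magnitude == pytest.approx(1.5)
        assert res.significance == pytest.approx(3.0)
        assert res.impact == pytest.approx(180.0)
        assert res.direction == pytest.approx(1 / 3)
        assert res.flux == pytest.approx(60.0)
        assert res.deg_members == ("g01", "g02")

    def test_disjoint_set_scores_zero(self, fixture_bundle):
        gs = GeneSet("null", "", frozenset({"g05", "g06", "g07"}))
        res = compute_impact(gs, fixture_bundle.table)
        assert res.impact == 0.0 and res.flux == 0.0 and res.n_deg == 0

    def test_empty_background_zero_result(self, fixture_bundle):
        gs = GeneSet("offworld", "", frozenset({"zz1", "zz2"}))
        res = compute_impact(gs, fixture_bundle.table)
        assert res.n_background == 0 and res.impact == 0.0

    def test_single_signed_deg_gives_flux_equal_impact(self):
        table = make_table([("a", 1.0, 0.1, 0.05), ("b", 1.0, 0.1, 0.05)])
        res = compute_impact(GeneSet("S", "", frozenset({"a", "b"})), table)
        assert res.proportion == 1.0 and res.magnitude == 1.0
        assert res.significance == pytest.approx(1.0)
        assert res.impact == pytest.approx(100.0)
        assert res.direction == 1.0 and res.flux == res.impact

    def test_count_direction_variant(self):
        table = make_table([("a", 3.0, 0.01, 0.02), ("b", -1.0, 0.01, 0.02)])
        gs = GeneSet("S", "", frozenset({"a", "b"}))
        magnitude = compute_impact(gs, table, direction_method="magnitude")
        count = compute_impact(gs, table, direction_method="count")
        assert magnitude.direction == pytest.approx(0.5)
        assert count.direction == pytest.approx(0.0)

    def test_adjusted_p_flag_changes_significance(self):
        table = make_table([("a", 1.0, 0.001, 0.01)])
        gs = GeneSet("S", "", frozenset({"a"}))
        raw = compute_impact(gs, table)
        adj = compute_impact(gs, table, use_adjusted_p=True)
        assert raw.significance == pytest.approx(3.0)
        assert adj.significance == pytest.approx(2.0)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_flux_bound_and_direction_range(self, data):
        """|F| <= I always; d in [-1, 1]; equality iff single-signed DEG."""
        n = data.draw(st.integers(1, 8))
        rows = []
        for i in range(n):
            lfc = data.draw(
                st.floats(-4, 4, allow_nan=False).filter(lambda x: abs(x) > 1e-6)
            )
            p = data.draw(st.floats(1e-6, 1.0, exclude_max=False))
            fdr = data.draw(st.floats(0, 1))
            rows.append((f"g{i}", lfc, p, fdr))
        table = make_table(rows)
        gs = GeneSet("S", "", frozenset(r[0] for r in rows))
        res = compute_impact(gs, table, 0.10)
        assert -1.0 <= res.direction <= 1.0
        assert abs(res.flux) <= res.impact + 1e-9
        if res.n_deg:
            signs = {table[g].log2fc > 0 for g in res.deg_members}
            if len(signs) == 1:
                assert abs(res.flux) == pytest.approx(res.impact)
                assert abs(res.direction) == pytest.approx(1.0)

    def test_doubling_fold_changes_doubles_impact(self):
        rows = [("a", 1.0, 0.01, 0.02), ("b", -0.5, 0.02, 0.03), ("c", 0.3, 0.5, 0.8)]
        doubled = [(g, 2 * l, p, f) for g, l, p, f in rows]
        gs = GeneSet("S", "", frozenset(r[0] for r in rows))
        base = compute_impact(gs, make_table(rows))
        twice = compute_impact(gs, make_table(doubled))
        assert twice.impact == pytest.approx(2 * base.impact)
        assert twice.direction == pytest.approx(base.direction)

    def test_deg_outside_set_leaves_impact_unchanged(self):
        rows = [("a", 1.0, 0.01, 0.02), ("b", -0.5, 0.3, 0.6)]
        extra = rows + [("z", 3.0, 0.001, 0.01)]
        gs = GeneSet("S", "", frozenset({"a", "b"}))
        assert compute_impact(gs, make_table(rows)).impact == pytest.approx(
            compute_impact(gs, make_table(extra)).impact
        )


class TestScoreCollection:
    def test_matches_per_set_calls_and_order(self, fixture_bundle):
        results = score_collection(fixture_bundle.sets, fixture_bundle.table)
        by_id = {r.set_id: r for r in results}
        for gs in fixture_bundle.sets:
            assert by_id[gs.set_id] == compute_impact(gs, fixture_bundle.table)
        impacts = [r.impact for r in results]
        assert impacts == sorted(impacts, reverse=True)

    def test_input_order_irrelevant(self, fixture_bundle):
        sets = list(fixture_bundle.sets)
        forward = score_collection(GeneSetCollection(sets), fixture_bundle.table)
        backward = score_collection(GeneSetCollection(sets[::-1]), fixture_bundle.table)
        assert forward == backward

    def test_matches_naive_reimplementation(self, default_bundle):
        results = score_collection(default_bundle.sets, default_bundle.table)
        for res in results:
            impact, flux = naive_impact(
                default_bundle.sets[res.set_id].members, default_bundle.table
            )
            assert res.impact == pytest.approx(impact, abs=1e-9)
            assert res.flux == pytest.approx(flux, abs=1e-9)


class TestAggregateHierarchy:
    HIER = PathwayHierarchy(
        {
            "P1": HierarchyEntry("one", "sc1", "cat"),
            "P2": HierarchyEntry("two", "sc1", "cat"),
            "P3": HierarchyEntry("three", "sc2", "cat"),
        }
    )

    @staticmethod
    def result(set_id, impact, flux, n_background=5, n_deg=1):
        return ImpactResult(
            set_id=set_id,
            n_background=n_background,
            n_deg=n_deg,
            proportion=n_deg / n_background if n_background else 0.0,
            magnitude=1.0,
            significance=1.0,
            impact=impact,
            direction=(flux / impact) if impact else 0.0,
            flux=flux,
            deg_members=(),
        )

    def test_hand_mean(self):
        results = [self.result("P1", 100, 50), self.result("P2", 200, -100)]
        (agg,) = aggregate_hierarchy(results, self.HIER, "subcategory")
        assert agg.group_id == "sc1"
        assert agg.impact == pytest.approx(150.0)
        assert agg.flux == pytest.approx(-25.0)
        assert agg.n_pathways == 2

    def test_single_pathway_group_is_identity(self):
        results = [self.result("P3", 42.0, -21.0)]
        (agg,) = aggregate_hierarchy(results, self.HIER, "subcategory")
        assert (agg.impact, agg.flux, agg.n_pathways) == (42.0, -21.0, 1)

    def test_empty_background_pathway_excluded(self):
        results = [
            self.result("P1", 100, 50),
            self.result("P2", 0.0, 0.0, n_background=0, n_deg=0),
        ]
        (agg,) = aggregate_hierarchy(results, self.HIER, "subcategory")
        assert agg.impact == pytest.approx(100.0) and agg.n_pathways == 1

    def test_unknown_pathway_skipped(self):
        results = [self.result("P1", 10, 5), self.result("QQ", 99, 99)]
        aggs = aggregate_hierarchy(results, self.HIER, "category")
        assert [a.group_id for a in aggs] == ["cat"]
        assert aggs[0].impact == pytest.approx(10.0)


class TestRankTop:
    RESULTS = [
        TestAggregateHierarchy.result("A", 50, 10),
        TestAggregateHierarchy.result("B", 80, -5),
        TestAggregateHierarchy.result("C", 60, 3),
    ]

    def test_hand_sort_up(self):
        assert [r.set_id for r in rank_top(self.RESULTS, 2, "up")] == ["C", "A"]

    def test_down_and_empty(self):
        assert [r.set_id for r in rank_top(self.RESULTS, 2, "down")] == ["B"]
        only_down = [TestAggregateHierarchy.result("X", 10, -1)]
        assert rank_top(only_down, 3, "up") == []

    def test_n_larger_than_qualifying(self):
        assert len(rank_top(self.RESULTS, 10, "up")) == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            rank_top(self.RESULTS, 0, "up")
        with pytest.raises(ValidationError):
            rank_top(self.RESULTS, 1, "sideways")
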