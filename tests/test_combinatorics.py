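"""Ground types, tuple enumeration, 4-partitions and the overlap graph."""

from itertools import product
from math import comb

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taxontrace as tt
from taxontrace.combinatorics import CTuple, FourPartition

from conftest import collection


def brute_force_4partitions(n):
    """Independent oracle: all block assignments, deduplicated."""
    seen = set()
    labels = list(range(n))
    for assignment in product(range(4), repeat=n):
        blocks = [frozenset(i for i, a in zip(labels, assignment) if a == b) for b in range(4)]
        if all(blocks):
            seen.add(frozenset(blocks))
    return len(seen)


class TestTupleEnumeration:
    def test_induced_examples(self, fx):
        got = tt.induced_ctuples(fx["ex2.5"], 4)
        assert {t.as_set() for t in got} == {
            frozenset(map(str, q))
            for q in [(1, 2, 3, 4), (1, 2, 3, 5), (1, 3, 4, 5), (2, 3, 4, 5)]
        }
        full = collection([(1, 2, 3, 4, 5)], 5)
        assert len(tt.induced_ctuples(full, 4)) == 5
        small = tt.TaxonSetCollection.of_integers([(1, 2), (3,)])
        assert len(tt.induced_ctuples(small, 4)) == 0

    def test_cross_examples(self, fx):
        assert [t.members for t in tt.cross_ctuples(fx["ex2.5"], 4)] == [
            ("1", "2", "4", "5")
        ]
        got = {t.as_set() for t in tt.cross_ctuples(fx["ex3.3"], 4)}
        assert got == {
            frozenset(map(str, q))
            for q in [(1, 2, 3, 4), (1, 3, 4, 5), (2, 4, 5, 6), (3, 4, 5, 6)]
        }
        with_x = collection([(1, 2, 3, 4, 5, 6)], 6)
        assert len(tt.cross_ctuples(with_x, 4)) == 0

    def test_invalid_c(self, fx):
        with pytest.raises(ValueError):
            tt.induced_ctuples(fx["ex2.5"], 0)
        with pytest.raises(ValueError):
            tt.cross_ctuples(fx["ex2.5"], -1)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_induced_cross_complement(self, data):
        n = data.draw(st.integers(4, 7))
        c = data.draw(st.integers(1, 4))
        k = data.draw(st.integers(0, 5))
        sets = [
            data.draw(
                st.sets(st.integers(1, n), min_size=0, max_size=n)
            )
            for _ in range(k)
        ]
        S = collection(sets, n)
        assert len(tt.induced_ctuples(S, c)) + len(
            tt.cross_ctuples(S, c)
        ) == comb(n, c)


class TestFourPartitions:
    @pytest.mark.parametrize("n,count", [(4, 1), (5, 10), (6, 65)])
    def test_counts(self, n, count):
        U = tt.TaxonUniverse.of_size(n)
        assert sum(1 for _ in tt.enumerate_4partitions(U)) == count

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force(self, n):
        U = tt.TaxonUniverse.of_size(n)
        got = sum(1 for _ in tt.enumerate_4partitions(U))
        assert got == brute_force_4partitions(n)

    @pytest.mark.parametrize("n", range(4, 10))
    def test_matches_stirling(self, n):
        U = tt.TaxonUniverse.of_size(n)
        parts = list(tt.enumerate_4partitions(U))
        assert len(parts) == tt.stirling2(n, 4)
        assert len(set(parts)) == len(parts)  # each exactly once

    def test_too_small(self):
        with pytest.raises(ValueError):
            list(tt.enumerate_4partitions(tt.TaxonUniverse.of_size(3)))

    def test_canonical_equality(self, u6):
        a = FourPartition.of(u6, [["5", "6"], ["1"], ["3", "4"], ["2"]])
        b = FourPartition.of(u6, [["1"], ["2"], ["4", "3"], ["6", "5"]])
        assert a == b

    def test_coverage(self, u6):
        p = FourPartition.of(u6, [["1"], ["2"], ["3"], ["4", "5", "6"]])
        q = tt.CTupleSet.build(u6, 4, [["1", "2", "3", "5"]])
        assert tt.partition_covered(p, q)
        p2 = FourPartition.of(u6, [["1"], ["2"], ["3", "4"], ["5", "6"]])
        q2 = tt.CTupleSet.build(u6, 4, [["1", "2", "3", "4"]])
        assert not tt.partition_covered(p2, q2)
        empty = tt.CTupleSet.build(u6, 4, [])
        assert not tt.partition_covered(p, empty)


class TestOverlapGraph:
    def test_neighbor_examples(self, u6, u5):
        t = CTuple.of(u6, ["1", "2", "3", "4"])
        assert len(tt.overlap_neighbors(t, u6)) == 8
        t5 = CTuple.of(u5, ["1", "2", "3", "4"])
        got = {x.members for x in tt.overlap_neighbors(t5, u5)}
        assert got == {
            ("1", "2", "3", "5"),
            ("1", "2", "4", "5"),
            ("1", "3", "4", "5"),
            ("2", "3", "4", "5"),
        }
        u4 = tt.TaxonUniverse.of_size(4)
        assert len(tt.overlap_neighbors(CTuple.of(u4, "1234"), u4)) == 0

    @pytest.mark.parametrize(
        "n,c", [(n, c) for n in range(1, 9) for c in range(1, n + 1)]
    )
    def test_neighbor_count_formula(self, n, c):
        U = tt.TaxonUniverse.of_size(n)
        t = CTuple.of(U, [str(i) for i in range(1, c + 1)])
        assert len(tt.overlap_neighbors(t, U)) == c * (n - c)

    def test_restriction_is_clique_on_cplus1(self, u6):
        g = tt.restrict_overlap_graph(u6, 4, ["1", "2", "3", "4", "6"])
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 10
        single = tt.restrict_overlap_graph(u6, 4, ["1", "2", "3", "4"])
        assert single.number_of_nodes() == 1
        assert single.number_of_edges() == 0

    def test_full_graph_connected(self):
        # connectivity of the overlap graph for every 1 <= c < n <= 7
        for n in range(2, 8):
            U = tt.TaxonUniverse.of_size(n)
            for c in range(1, n):
                g = tt.restrict_overlap_graph(U, c, U.labels)
                assert nx.is_connected(g), (n, c)

    def test_restriction_too_small(self, u6):
        with pytest.raises(ValueError):
            tt.restrict_overlap_graph(u6, 4, ["1", "2"])


class TestTypes:
    def test_universe_validation(self):
        with pytest.raises(ValueError):
            tt.TaxonUniverse(())
        with pytest.raises(ValueError):
            tt.TaxonUniverse(("a", "a"))

    def test_collection_membership(self, u5):
        with pytest.raises(ValueError):
            tt.TaxonSetCollection(u5, (frozenset({"9"}),))

    def test_empty_member_sets_allowed(self, u5):
        S = tt.TaxonSetCollection(u5, (frozenset(),))
        assert len(tt.induced_ctuples(S, 4)) == 0

    def test_ctuple_canonical_order(self, u6):
        assert CTuple.of(u6, ["4", "1", "3"]).members == ("1", "3", "4")
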