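"""Fixing taxa, the coloring algorithm, certificates and the extremes."""

import random
from math import comb

import pytest

import taxontrace as tt
from taxontrace._fast import kernel
from taxontrace.combinatorics import CTuple

from conftest import collection


class TestFixingTaxa:
    def test_worked_examples(self, fx):
        s3 = fx["ex3.3"]
        white = tt.induced_ctuples(s3, 4)
        U = s3.universe
        assert tt.fixing_taxa(CTuple.of(U, "1234"), white) == {"6"}
        assert tt.fixing_taxa(CTuple.of(U, "1345"), white) == set()
        assert tt.fixing_taxa(CTuple.of(U, "2456"), white) == {"1"}
        s25 = fx["ex2.5"]
        white25 = tt.induced_ctuples(s25, 4)
        assert tt.fixing_taxa(
            CTuple.of(s25.universe, "1245"), white25
        ) == {"3"}

    def test_rejects_already_white_tuple(self, fx):
        s = fx["ex2.5"]
        white = tt.induced_ctuples(s, 4)
        with pytest.raises(ValueError):
            tt.fixing_taxa(CTuple.of(s.universe, "1234"), white)


class TestTrace:
    def test_traceable_example_resolves_all_four(self, fx):
        cert = tt.trace(fx["ex3.8"], 4)
        assert cert.traceable
        assert cert.initial_cross_count == 4
        assert cert.resolved_count == 4

    def test_nontraceable_example_resolves_nothing(self, fx):
        cert = tt.trace(fx["ex3.10"], 4)
        assert not cert.traceable
        assert cert.initial_cross_count == 6
        assert cert.resolved_count == 0

    def test_triple_traceability(self, fx):
        cert = tt.trace(fx["ex3.19"], 3)
        assert cert.traceable and cert.resolved_count == 1
        assert cert.steps[0].resolved_tuple.members == ("1", "2", "3")

    def test_no_cross_tuples(self):
        cert = tt.trace(collection([(1, 2, 3, 4, 5)], 5), 4)
        assert cert.traceable and cert.resolved_count == 0

    def test_empty_collection_not_traceable(self):
        S = tt.TaxonSetCollection(tt.TaxonUniverse.of_size(5), ())
        cert = tt.trace(S, 4)
        assert not cert.traceable
        assert cert.initial_cross_count == 5 and cert.resolved_count == 0

    def test_c_larger_than_n(self):
        with pytest.raises(ValueError):
            tt.trace(collection([(1, 2, 3)], 3), 4)

    def test_step_invariants(self, fx):
        cert = tt.trace(fx["ex3.8"], 4)
        for i, step in enumerate(cert.steps, start=1):
            assert step.step_index == i
            assert step.fixing_taxon not in step.resolved_tuple.members

    @pytest.mark.parametrize("name", ["ex3.3", "ex3.10", "ex3.23i"])
    def test_order_independence(self, fx, name):
        S = fx[name]
        ref = tt.trace(S, 4)
        ref_resolved = {s.resolved_tuple for s in ref.steps}
        for seed in range(10):
            got = tt.trace(S, 4, shuffle_seed=seed)
            assert got.traceable == ref.traceable
            assert {s.resolved_tuple for s in got.steps} == ref_resolved

    def test_certificate_replay(self, fx):
        for name in ("ex2.5", "ex3.3", "ex3.10", "ex3.23ii"):
            S = fx[name]
            assert tt.trace(S, 4).replay(S)
        star = tt.star_construction(tt.TaxonUniverse.of_size(8))
        assert tt.trace(star).replay(star)

    def test_replay_rejects_forged_certificate(self, fx):
        from taxontrace.traceability import TraceCertificate, TraceStep

        S = fx["ex3.10"]
        forged = TraceCertificate(
            universe=S.universe,
            c=4,
            steps=(
                TraceStep(CTuple.of(S.universe, "1234"), "6", 1),
            ),
            traceable=False,
            initial_cross_count=6,
        )
        assert not forged.replay(S)

    def test_certificate_json(self, fx):
        import json

        payload = json.loads(tt.trace(fx["ex3.8"], 4).to_json())
        assert payload["traceable"] is True
        assert payload["initial_cross_count"] == 4
        assert len(payload["steps"]) == 4

    def test_step_count_bounded_on_generated_inputs(self):
        for n in range(6, 10):
            star = tt.star_construction(tt.TaxonUniverse.of_size(n))
            cert = tt.trace(star)
            assert cert.traceable
            assert cert.resolved_count == comb(n, 4) - comb(n - 1, 3)


class TestImplication:
    def test_ftt_implies_decisive_exhaustive_n5(self):
        ker = kernel(5, 4)
        for mask in range(ker.full_mask + 1):
            if ker.is_traceable(mask):
                assert ker.is_decisive(mask)

    @pytest.mark.parametrize("n,draws", [(6, 1000), (7, 200)])
    def test_ftt_implies_decisive_sampled(self, n, draws):
        ker = kernel(n, 4)
        rng = random.Random(n)
        for _ in range(draws):
            mask = rng.getrandbits(ker.total)
            if ker.is_traceable(mask):
                assert ker.is_decisive(mask)

    def test_converse_fails_on_fixed_counterexamples(self, fx):
        for name in ("ex3.10", "ex3.23i", "ex3.23ii"):
            S = fx[name]
            assert tt.is_decisive_unrooted(S).decisive
            assert not tt.is_ftt(S)


class TestMonotonicityAndBounds:
    def test_traceable_stays_traceable_under_additions(self):
        ker = kernel(6, 4)
        rng = random.Random(3)
        for _ in range(200):
            base = rng.getrandbits(15)
            if ker.is_traceable(base):
                extra = base | rng.getrandbits(15)
                assert ker.is_traceable(extra)

    @pytest.mark.parametrize("n,c", [(5, 4), (6, 4), (5, 3)])
    def test_guarantee_threshold(self, n, c):
        # every family with at least C(n,c) - n + c tuples is traceable
        ker = kernel(n, c)
        threshold = comb(n, c) - n + c
        for k in range(threshold, ker.total + 1):
            assert all(
                ker.is_traceable(m) for m in ker.subsets_of_size(k)
            )

    @pytest.mark.parametrize(
        "n,c,expected", [(5, 4, 4), (6, 4, 10), (4, 3, 3)]
    )
    def test_min_ftt_size(self, n, c, expected):
        U = tt.TaxonUniverse.of_size(n)
        assert tt.min_ftt_size_exhaustive(U, c) == expected
        assert expected == comb(n - 1, c - 1)

    def test_min_ftt_guard(self):
        with pytest.raises(ValueError, match="force"):
            tt.min_ftt_size_exhaustive(tt.TaxonUniverse.of_size(7))

    def test_max_decisive_not_ftt(self):
        assert (
            tt.max_decisive_not_ftt_exhaustive(tt.TaxonUniverse.of_size(6))
            == 10
        )
        # the two properties coincide below 6 taxa
        assert (
            tt.max_decisive_not_ftt_exhaustive(tt.TaxonUniverse.of_size(5))
            == 0
        )


def test_colored_overlap_graph_colors(fx):
    g = tt.colored_overlap_graph(fx["ex3.3"], 4)
    colors = [d["color"] for _, d in g.nodes(data=True)]
    assert colors.count("gray") == 4 and colors.count("white") == 11
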