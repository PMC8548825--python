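"""Stage 2: hypergeometric tail, BH adjustment, enrichment, flag assignment."""

from itertools import combinations
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwas2drug import scoring
from gwas2drug.types import (
    CRITERIA,
    Consequence,
    CriterionVector,
    GeneRecord,
    GeneSetCollection,
    VariantAnnotation,
)


def enumeration_tail(k, K, n, N):
    """Independent oracle: P(X >= k) by exhaustive enumeration of all C(N, n)
    draws of n items from a universe of N containing K successes."""
    successes = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n) if len(successes & set(draw)) >= k)
    return hits / comb(N, n)


class TestHypergeomUpper:
    def test_zero_overlap_gives_one(self):
        assert scoring.hypergeom_upper(0, 4, 5, 10) == 1.0

    def test_all_universe_in_term_gives_one(self):
        assert scoring.hypergeom_upper(3, 10, 5, 10) == pytest.approx(1.0)

    def test_known_enumeration_value(self):
        # 66 of the C(10,5) = 252 draws contain >= 3 of the 4 successes
        assert enumeration_tail(3, 4, 5, 10) == 66 / 252
        assert scoring.hypergeom_upper(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_infeasible_arguments_rejected(self):
        with pytest.raises(ValueError):
            scoring.hypergeom_upper(5, 4, 5, 10)  # k > K
        with pytest.raises(ValueError):
            scoring.hypergeom_upper(1, 11, 5, 10)  # K > N

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_enumeration_exhaustively(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert scoring.hypergeom_upper(k, K, n, N) == pytest.approx(
                        enumeration_tail(k, K, n, N), abs=1e-12
                    ), (k, K, n, N)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert scoring.bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_step_up(self):
        # q(i) = min_{j>=i} p(j)*m/j: all four collapse to 0.04
        assert scoring.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_stay_equal(self):
        assert scoring.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_empty(self):
        assert scoring.bh_adjust([]) == []

    def test_returned_in_input_order(self):
        q = scoring.bh_adjust([0.04, 0.01])
        # sorted p: (0.01, 0.04) -> q (0.02, 0.04); unsorted input keeps order
        assert q == pytest.approx([0.04, 0.02])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=100)
    def test_q_capped_at_one_and_monotone_when_sorted(self, ps):
        ps = sorted(ps)
        q = scoring.bh_adjust(ps)
        assert all(x <= 1.0 + 1e-12 for x in q)
        assert all(a <= b + 1e-12 for a, b in zip(q, q[1:]))
        assert q[-1] >= ps[-1] - 1e-12


class TestEnrich:
    def toy_collection(self):
        universe = frozenset(f"U{i}" for i in range(10))
        sets = {
            "T1": frozenset({"U0", "U1", "U2", "U3"}),
            "T2": frozenset({"U7", "U8", "U9"}),
        }
        return GeneSetCollection(name="toy", sets=sets, universe=universe)

    def test_toy_collection_matches_composed_primitives(self):
        coll = self.toy_collection()
        query = {"U0", "U1", "U2", "U4", "U5"}  # overlaps: T1 -> 3, T2 -> 0
        results = {r.term_id: r for r in scoring.enrich(query, coll)}
        p1 = scoring.hypergeom_upper(3, 4, 5, 10)
        p2 = scoring.hypergeom_upper(0, 3, 5, 10)
        q1, q2 = scoring.bh_adjust([p1, p2])
        assert results["T1"].p == pytest.approx(p1)
        assert results["T2"].p == pytest.approx(p2) and results["T2"].p == 1.0
        assert results["T1"].q == pytest.approx(q1)
        assert results["T2"].q == pytest.approx(q2)
        assert not results["T2"].enriched

    def test_query_genes_outside_universe_excluded_from_n(self):
        coll = self.toy_collection()
        results = scoring.enrich({"U0", "U1", "NOT_THERE"}, coll)
        assert all(r.n == 2 for r in results)

    def test_empty_effective_query_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            scoring.enrich({"X1", "X2"}, self.toy_collection())

    def test_pid_rule_uses_raw_p(self):
        universe = frozenset(f"U{i}" for i in range(40))
        coll = GeneSetCollection(
            name="pid",
            sets={"PID1": frozenset({"U0", "U1"}), "PID2": frozenset({"U30", "U31"})},
            universe=universe,
        )
        query = {f"U{i}" for i in range(8)}
        by_fdr = {r.term_id: r for r in scoring.enrich(query, coll)}
        by_raw = {r.term_id: r for r in scoring.enrich(query, coll, raw_p_selection=True)}
        p = scoring.hypergeom_upper(2, 2, 8, 40)  # = C(8,2)/C(40,2) ~ 0.0359
        assert by_raw["PID1"].p == pytest.approx(p)
        assert by_raw["PID1"].enriched  # 0.0359 < 0.05 on the raw-p rule
        assert not by_fdr["PID1"].enriched  # but q = 2p > 0.05 under BH

    def test_min_term_size_filters_terms(self):
        coll = self.toy_collection()
        results = scoring.enrich({"U0"}, coll, min_term_size=4)
        assert [r.term_id for r in results] == ["T1"]

    @given(extra=st.sets(st.sampled_from([f"U{i}" for i in range(10)]), max_size=5))
    @settings(deadline=None, max_examples=30)
    def test_enlarging_query_never_decreases_overlap(self, extra):
        coll = self.toy_collection()
        base = {"U0", "U5"}
        k0 = {r.term_id: r.k for r in scoring.enrich(base, coll)}
        k1 = {r.term_id: r.k for r in scoring.enrich(base | extra, coll)}
        assert all(k1[t] >= k0[t] for t in k0)


class TestFlagsAndSelection:
    def make_gene(self, gid, symbol, snps):
        return GeneRecord(gene_id=gid, symbol=symbol, supporting_snps=frozenset(snps))

    def test_no_signals_gives_score_zero(self):
        g = self.make_gene("E1", "A", {"rs1"})
        classes = {"rs1": VariantAnnotation("rs1", Consequence.NONCODING)}
        v = scoring.assign_flags([g], classes, {})[0]
        assert v.score == 0 and not any(v.flags)

    def test_all_six_criteria_give_score_six(self):
        g = self.make_gene("E1", "A", {"rs1", "rs2"})
        classes = {
            "rs1": VariantAnnotation("rs1", Consequence.MISSENSE_NONSENSE),
            "rs2": VariantAnnotation(
                "rs2", Consequence.NONCODING, eqtl=True, eqtl_tissue="whole_blood"
            ),
        }
        sets = {c: frozenset({"A"}) for c in ("ko_mouse", "go_bp", "kegg", "pid")}
        v = scoring.assign_flags([g], classes, sets)[0]
        assert v.score == 6

    def test_eqtl_flag_requires_configured_tissue(self):
        g = self.make_gene("E1", "A", {"rs1"})
        classes = {
            "rs1": VariantAnnotation("rs1", Consequence.NONCODING, eqtl=True, eqtl_tissue="skin")
        }
        v = scoring.assign_flags([g], classes, {}, eqtl_tissue="whole_blood")[0]
        assert not v.eqtl

    def test_select_biological_sorts_and_is_idempotent(self):
        vs = [
            CriterionVector("E1", "B", missense=True, eqtl=True),
            CriterionVector("E2", "A", missense=True, eqtl=True, kegg=True),
            CriterionVector("E3", "C", missense=True),
        ]
        picked = scoring.select_biological(vs, 2)
        assert [v.gene_id for v in picked] == ["E2", "E1"]
        assert scoring.select_biological(picked, 2) == picked
        assert scoring.select_biological(vs, 0) == sorted(
            vs, key=lambda v: (-v.score, v.symbol, v.gene_id)
        )
        assert scoring.select_biological(vs, 7) == []

    def test_histogram_covers_all_bins_and_sums_to_gene_count(self):
        assert scoring.score_histogram([]) == {s: 0 for s in range(7)}
        vs = [CriterionVector("E1", "A"), CriterionVector("E2", "B", pid=True)]
        hist = scoring.score_histogram(vs)
        assert hist[0] == 1 and hist[1] == 1 and sum(hist.values()) == 2

    def test_score_sum_equals_flag_count_sum(self, stoch_bundle):
        """Conservation: total points over genes == total flags over criteria."""
        m = stoch_bundle.manifest
        vs = [
            CriterionVector("g", "g", **dict(zip(CRITERIA, flags)))
            for flags in m.flag_vectors.values()
        ]
        assert sum(v.score for v in vs) == sum(scoring.flag_counts(vs).values())
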