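"""Enrichment statistics, standards classification, HTP filtering, graph export."""

import random
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohnolynch.interactome_enrichment import (
    build_graph,
    classify_standards,
    export_graph,
    filter_htp,
    hypergeometric_pmf,
    hypergeometric_tail,
    overlap_stats,
)
from ohnolynch.ohnologue_families import OhnologPair, build_families
from ohnolynch.tabular_io import CaptureExperiment, DataError, PhosphositeRecord


def exact_tail(N, K, n, k):
    """Exact rational upper tail by direct binomial-coefficient arithmetic."""
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)),
        comb(N, n),
    )


class TestHypergeometricTail:
    def test_k_zero_is_one(self):
        assert hypergeometric_tail(50, 10, 5, 0) == 1.0

    def test_all_successes_small_case(self):
        # drawing all 5 marked from 10: 1/C(10,5) = 1/252
        assert hypergeometric_tail(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_enumeration_of_all_draws_n4(self):
        # N=4, K=2, n=2: of the 6 equally likely draws, 5 contain ≥1 marked
        assert hypergeometric_tail(4, 2, 2, 1) == pytest.approx(5 / 6, rel=1e-12)

    def test_matches_exact_rationals_for_all_small_parameters(self):
        for N in range(13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeometric_tail(N, K, n, k)
                        assert got == pytest.approx(
                            float(exact_tail(N, K, n, k)), abs=1e-12
                        )

    def test_pmf_sums_to_one_at_large_N(self):
        for N, K, n in [(10**5, 30_000, 5_000), (10**5, 7104, 207), (50_000, 49_999, 1)]:
            total = sum(
                hypergeometric_pmf(N, K, n, k)
                for k in range(max(0, n + K - N), min(K, n) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_tail_non_increasing_and_symmetric(self):
        N, K, n = 200, 40, 25
        tails = [hypergeometric_tail(N, K, n, k) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        for k in range(min(K, n) + 1):
            assert hypergeometric_tail(N, K, n, k) == pytest.approx(
                hypergeometric_tail(N, n, K, k), rel=1e-10
            )

    def test_matches_scipy_cross_check(self):
        from scipy.stats import hypergeom

        for N, K, n, k in [(20244, 7104, 207, 174), (1000, 100, 50, 12)]:
            assert hypergeometric_tail(N, K, n, k) == pytest.approx(
                float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
            )

    def test_invalid_parameters_are_hard_errors(self):
        for args in [(10, 11, 5, 0), (10, 5, 5, 6), (-1, 0, 0, 0), (10, 5, 11, 0)]:
            with pytest.raises(DataError):
                hypergeometric_tail(*args)


class TestClassifyStandards:
    def test_gold_from_sites_and_disjointness(self):
        sites = [PhosphositeRecord("P1", 3, "S", "gold")]
        std = classify_standards(sites, {"P1", "P2"})
        assert std.gold == {"P1"}
        assert std.silver == {"P2"}  # P1 dropped from silver: tiers are disjoint

    def test_reference_fixture_standards_counts(self, reference_fixture):
        std = classify_standards(
            reference_fixture.sites, reference_fixture.silver_list
        )
        assert len(std.gold) == 172 and len(std.silver) == 35


class TestOverlapStats:
    @staticmethod
    def _fs():
        pairs = [OhnologPair("P1", "P2"), OhnologPair("P3", "P4"), OhnologPair("P4", "P5")]
        uni = {f"P{i}" for i in range(1, 11)}
        return build_families(pairs, uni), uni

    def test_disjoint_query(self):
        fs, uni = self._fs()
        r = overlap_stats({"P8", "P9"}, fs, uni)
        assert r.k == 0 and r.p_hyper == 1.0 and r.n_families == 0

    def test_hand_counted_family_hits(self):
        fs, uni = self._fs()
        r = overlap_stats({"P1", "P3", "P9"}, fs, uni)
        assert (r.k, r.n_families, r.n_members_total) == (2, 2, 5)

    def test_query_outside_universe_rejected(self):
        fs, uni = self._fs()
        with pytest.raises(DataError):
            overlap_stats({"PX"}, fs, uni)


class TestFilterHtp:
    def test_inclusion_exclusion_logic(self):
        fs = build_families([OhnologPair("a", "b")], {"a", "b", "c"})
        exps = [CaptureExperiment("E1", frozenset({"a", "b", "c"}))]
        kept, _ = filter_htp(exps, {"a", "b", "c"}, {"c"}, fs)
        assert kept == {"a", "b"}
        kept2, _ = filter_htp(exps, {"a", "b", "c"}, set(), fs)
        assert kept2 == {"a", "b", "c"}

    @given(
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kept_within_inclusion_and_disjoint_from_exclusion(
        self, captured, inclusion, exclusion
    ):
        names = {i: f"P{i}" for i in range(31)}
        uni = set(names.values())
        fs = build_families([OhnologPair("P0", "P1")], uni)
        exps = [CaptureExperiment("E1", frozenset(names[i] for i in captured))]
        incl = {names[i] for i in inclusion}
        excl = {names[i] for i in exclusion}
        kept, _ = filter_htp(exps, incl, excl, fs, universe=uni)
        assert kept <= incl and not (kept & excl)


class TestGraphExport:
    @staticmethod
    def _graph():
        fs = build_families([OhnologPair("P1", "P2")], {"P1", "P2", "P3"})
        exps = [CaptureExperiment("E1", frozenset({"P1", "P2"}))]
        std = classify_standards(
            [PhosphositeRecord("P1", 1, "S", "gold")], set()
        )
        return build_graph(exps, std, {"P1", "P2"}, fs)

    def test_node_and_edge_counts(self):
        g = self._graph()
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_class_priority_gold_over_contaminant(self):
        g = self._graph()
        assert g.nodes["P1"]["klass"] == "gold"          # also a contaminant
        assert g.nodes["P2"]["klass"] == "contaminant"

    def test_edge_count_identity_over_studies(self, small_bundle):
        from ohnolynch.ohnologue_families import build_families as bf
        from ohnolynch.interactome_enrichment import StandardsSet

        b = small_bundle
        fs = bf(b.pairs, b.idmap.genes)
        g = build_graph(
            b.experiments,
            StandardsSet(gold=frozenset(), silver=frozenset()),
            b.contaminants,
            fs,
            idmap=b.idmap,
        )
        assert g.number_of_edges() == sum(len(e.protein_accs) for e in b.experiments)

    def test_exports_deterministic_byte_for_byte(self, tmp_path):
        g = self._graph()
        for dialect, name in [("graphml", "g.graphml"), ("visant_xml", "g.xml")]:
            p1, p2 = tmp_path / f"1{name}", tmp_path / f"2{name}"
            export_graph(g, p1, dialect)
            export_graph(self._graph(), p2, dialect)
            assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(DataError):
            export_graph(self._graph(), tmp_path / "x", "gexf")
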