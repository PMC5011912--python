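"""The hypergeometric null, the discrete two-sided p-value, and batch runs."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from neat import (
    NetworkError,
    NodeSet,
    NullParams,
    build_network,
    expand_mixed,
    hypergeom_pmf,
    neat,
    null_params,
    two_sided_pvalue,
)
from neat.enrichment import _double_tail_pvalue


def exact_two_sided(t, n, K, N):
    """Independent oracle: exact rational arithmetic over the support."""
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    pmf = {k: Fraction(comb(K, k) * comb(N - K, n - k), denom)
           for k in range(lo, hi + 1)}
    below = sum((v for k, v in pmf.items() if k < t), Fraction(0))
    above = sum((v for k, v in pmf.items() if k > t), Fraction(0))
    return float(2 * min(below, above) + pmf.get(t, Fraction(0)))


params_strategy = st.integers(1, 400).flatmap(
    lambda N: st.tuples(
        st.integers(0, N), st.integers(0, N), st.just(N)
    )
)


class TestPmf:
    def test_exact_value(self):
        # C(4,2)*C(11,3)/C(15,5) = 990/3003
        assert hypergeom_pmf(2, NullParams(5, 4, 15)) == pytest.approx(
            990 / 3003, abs=1e-12
        )

    def test_all_population_successes(self):
        assert hypergeom_pmf(7, NullParams(7, 20, 20)) == pytest.approx(1.0)

    def test_zero_outside_support(self):
        p = NullParams(5, 4, 15)
        assert hypergeom_pmf(5, p) == 0.0
        assert hypergeom_pmf(-1, p) == 0.0

    @given(params_strategy)
    @settings(max_examples=200, deadline=None)
    def test_normalization(self, params):
        n, K, N = params
        p = NullParams(n, K, N)
        lo, hi = p.support
        total = sum(hypergeom_pmf(k, p) for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(2, 2000))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            ours = hypergeom_pmf(k, NullParams(n, K, N))
            ref = hypergeom.pmf(k, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


class TestTwoSidedPvalue:
    @pytest.mark.parametrize(
        "t,n,K,N,printed,places",
        [
            (2, 5, 4, 15, 0.48, 2),
            (3, 4, 4, 15, 0.03, 2),
            (4, 4, 15, 36, 0.023, 3),
            (0, 4, 6, 36, 0.465, 3),
            (5, 15, 6, 36, 0.038, 3),
        ],
    )
    def test_worked_examples_at_printed_precision(self, t, n, K, N, printed, places):
        assert round(two_sided_pvalue(t, NullParams(n, K, N)), places) == printed

    def test_point_mass_null_gives_one(self):
        # K = N: every sampled arrow is a success, T = n with certainty
        assert two_sided_pvalue(6, NullParams(6, 19, 19)) == 1.0
        assert two_sided_pvalue(0, NullParams(0, 4, 15)) == 1.0

    @given(params_strategy, st.integers(-2, 400))
    @settings(max_examples=300, deadline=None)
    def test_in_unit_interval(self, params, t):
        n, K, N = params
        p = two_sided_pvalue(t, NullParams(n, K, N))
        assert 0.0 <= p <= 1.0

    @given(params_strategy)
    @settings(max_examples=200, deadline=None)
    def test_differs_from_doubled_tail_by_point_mass(self, params):
        n, K, N = params
        null = NullParams(n, K, N)
        lo, hi = null.support
        t = lo + (hi - lo) // 2
        p = two_sided_pvalue(t, null)
        p1 = _double_tail_pvalue(t, null)
        assert p == pytest.approx(p1 - hypergeom_pmf(t, null), abs=1e-9)

    @given(params_strategy)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_sample_and_successes(self, params):
        # hypergeom pmf is symmetric in n and K, so the undirected test
        # gives the same p-value when A and B are swapped
        n, K, N = params
        t = min(n, K)
        assert two_sided_pvalue(t, NullParams(n, K, N)) == pytest.approx(
            two_sided_pvalue(t, NullParams(K, n, N)), abs=1e-12
        )

    def test_matches_exact_enumeration_spot_checks(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(1, 31))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(n, K)
            t = int(rng.integers(lo, hi + 1))
            assert two_sided_pvalue(t, NullParams(n, K, N)) == pytest.approx(
                exact_two_sided(t, n, K, N), abs=1e-12
            )

    def test_extreme_tail_no_cancellation(self):
        # smaller tail summed directly: far-tail p-values stay positive
        p = two_sided_pvalue(150, NullParams(400, 400, 4000))
        assert 0.0 < p < 1e-30

    def test_invalid_params_rejected(self):
        with pytest.raises(NetworkError):
            NullParams(5, 20, 15)


class TestNullParams:
    def test_worked_example_expectations(self):
        assert round(NullParams(5, 4, 15).mu0, 2) == 1.33
        assert round(NullParams(4, 4, 15).mu0, 2) == 1.07
        assert round(NullParams(4, 15, 36).mu0, 2) == 1.67

    def test_from_network_directed(self, directed_example_net, directed_example_sets):
        p = null_params(directed_example_net, directed_example_sets["A"], directed_example_sets["B"])
        assert (p.n, p.K, p.N) == (5, 4, 15)
        p = null_params(directed_example_net, directed_example_sets["B"], directed_example_sets["C"])
        assert (p.n, p.K, p.N) == (4, 4, 15)

    def test_from_network_undirected(self, undirected_example_net, undirected_example_sets):
        p = null_params(undirected_example_net, undirected_example_sets["A"], undirected_example_sets["B"])
        assert (p.n, p.K, p.N) == (4, 15, 36)
        assert round(p.mu0, 2) == 1.67

    def test_edgeless_network_is_an_error(self):
        net = build_network([(1, 2)], "directed")
        empty = build_network([], "directed", nodes=net.nodes)
        with pytest.raises(NetworkError, match="no links"):
            null_params(empty, NodeSet("a", [1]), NodeSet("b", [2]))

    def test_degenerate_source_flagged_and_p_is_one(self):
        net = build_network([(1, 2), (3, 2)], "directed")
        sink_only = NodeSet("sink", [2])  # outdegree zero
        p = null_params(net, sink_only, NodeSet("b", [1]))
        assert p.n == 0 and p.degenerate
        assert two_sided_pvalue(0, p) == 1.0


class TestBatch:
    def test_directed_worked_example_no_evidence(self, directed_example_net, directed_example_sets):
        rows = neat(directed_example_net, [directed_example_sets["A"]], [directed_example_sets["B"]], alpha=0.05)
        assert len(rows) == 1
        assert rows[0].conclusion == "no evidence"
        assert round(rows[0].pvalue, 2) == 0.48

    def test_directed_b_to_c_enriched(self, directed_example_net, directed_example_sets):
        row = neat(directed_example_net, [directed_example_sets["B"]], [directed_example_sets["C"]], alpha=0.05)[0]
        assert row.conclusion == "over-enriched"
        assert round(row.pvalue, 2) == 0.03

    def test_undirected_example_verdicts(self, undirected_example_net, undirected_example_sets):
        sets = list(undirected_example_sets.values())
        rows = neat(undirected_example_net, sets, sets, alpha=0.05)
        verdicts = {(r.set_a, r.set_b): r.conclusion for r in rows}
        assert len(rows) == 6  # 3 unordered pairs + 3 self pairs
        assert verdicts[("A", "B")] == "over-enriched"
        assert verdicts[("B", "C")] == "over-enriched"
        assert verdicts[("A", "C")] == "no evidence"
        pvals = {(r.set_a, r.set_b): round(r.pvalue, 3) for r in rows}
        assert pvals[("A", "B")] == 0.023
        assert pvals[("A", "C")] == 0.465
        assert pvals[("B", "C")] == 0.038

    def test_self_pair_is_legal(self, undirected_example_net, undirected_example_sets):
        s = undirected_example_sets["B"]
        rows = neat(undirected_example_net, [s], [s])
        assert len(rows) == 1
        assert 0.0 <= rows[0].pvalue <= 1.0

    def test_undirected_pairs_deduplicated_lexicographic(self, undirected_example_net, undirected_example_sets):
        sets = [undirected_example_sets["C"], undirected_example_sets["A"]]
        rows = neat(undirected_example_net, sets, sets)
        names = [(r.set_a, r.set_b) for r in rows]
        assert names == [("C", "C"), ("A", "C"), ("A", "A")]

    def test_directed_ordered_pairs_both_ways(self, directed_example_net, directed_example_sets):
        a, b = directed_example_sets["A"], directed_example_sets["B"]
        rows = neat(directed_example_net, [a, b], [a, b])
        names = [(r.set_a, r.set_b) for r in rows]
        assert names == [("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")]

    def test_empty_set_list_is_an_error(self, directed_example_net):
        with pytest.raises(NetworkError, match="empty"):
            neat(directed_example_net, [], [])

    def test_expansion_equals_undirected_test(self, undirected_example_net, undirected_example_sets):
        mixed = build_network(
            [(u, v, "undirected") for u, v in undirected_example_net.edge_records()],
            "mixed",
        )
        image = expand_mixed(mixed)
        a, b = undirected_example_sets["A"], undirected_example_sets["B"]
        p_und = null_params(undirected_example_net, a, b)
        p_dir = null_params(image, a, b)
        assert (p_dir.n, p_dir.K, p_dir.N) == (p_und.n, p_und.K, p_und.N)
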