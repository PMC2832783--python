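import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pogf import (
    GeneList,
    ModularNetworkSpec,
    ParameterError,
    PPINetwork,
    functionally_similar,
    generate_network,
    link_enrichment_pvalue,
    link_test_table,
    prioritize,
    select_by_benchmark,
)
from pogf.similarity import significance_k_threshold, _upper_tail
from conftest import random_network


class TestLinkEnrichmentPvalue:
    def test_zero_links_gives_p_one(self, two_components_net):
        t = link_enrichment_pvalue(
            two_components_net, "A", GeneList("L", ("C", "D"))
        )
        assert t.k == 0 and t.p == 1.0

    def test_list_off_network_gives_p_one(self, star_net):
        t = link_enrichment_pvalue(star_net, "H", GeneList("L", ("X",)))
        assert t.M == 0 and t.p == 1.0

    def test_counts_on_star(self, star_net):
        # L1 links H and all leaves (n=4); both list genes are partners
        t = link_enrichment_pvalue(star_net, "L1", GeneList("L", ("H", "L2")))
        assert (t.k, t.n, t.M, t.N) == (2, 4, 2, 4)
        # p = P(X >= 2), X ~ Hypergeom(N=4, M=2, n=4) = 1 (all partners drawn)
        assert t.p == pytest.approx(1.0)

    def test_membership_in_target_reduces_M(self, star_net):
        t = link_enrichment_pvalue(star_net, "L1", GeneList("L", ("L1", "L2")))
        assert t.M == 1 and t.k == 1

    def test_monotone_nonincreasing_in_k(self):
        N, M, n = 40, 8, 10
        ps = _upper_tail(np.arange(0, 9), N, M, n)
        assert (np.diff(ps) <= 1e-12).all()


class TestFunctionallySimilar:
    def test_strict_threshold(self):
        # star plus isolated background: leaf vs {hub} has p = n/N = 4/19
        net = PPINetwork(
            [("H", f"L{i}") for i in range(1, 5)],
            nodes=[f"Z{i:02d}" for i in range(15)],
        )
        hub = GeneList("L", ("H",))
        p = link_enrichment_pvalue(net, "L1", hub).p
        assert p == pytest.approx(4 / 19)
        assert not functionally_similar(net, "L1", hub, alpha=p)
        assert functionally_similar(net, "L1", hub, alpha=p + 1e-9)

    def test_isolated_gene_never_similar(self):
        net = PPINetwork([("A", "B")], nodes=["Z"])
        assert not functionally_similar(net, "Z", GeneList("L", ("A", "B")))

    def test_alpha_validated(self, star_net):
        with pytest.raises(ParameterError):
            functionally_similar(star_net, "L1", GeneList("L", ("H",)), alpha=1.5)


class TestLinkTestTable:
    @given(st.integers(0, 10_000))
    def test_matches_single_gene_tests(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_nodes=15, p=0.2)
        target = GeneList("T", tuple(rng.choice(net.node_list, 6, replace=False)))
        query = GeneList("Q", tuple(rng.choice(net.node_list, 8, replace=False)))
        table = link_test_table(net, query, target)
        for t in table:
            single = link_enrichment_pvalue(net, t.gene, target)
            assert (t.k, t.n, t.M) == (single.k, single.n, single.M)
            assert t.p == pytest.approx(single.p)

    def test_off_network_query_gets_p_one(self, star_net):
        table = link_test_table(
            star_net, GeneList("Q", ("H", "X")), GeneList("T", ("L1", "L2"))
        )
        assert table[1].gene == "X" and table[1].p == 1.0


class TestSignificanceThreshold:
    @given(
        st.integers(5, 60),
        st.integers(1, 12),
        st.sampled_from([0.01, 0.05, 0.2]),
    )
    def test_threshold_reproduces_direct_test(self, N, M, alpha):
        M = min(M, N)
        n_max = N
        kmin = significance_k_threshold(N, M, n_max, alpha)
        for n in range(n_max + 1):
            for k in range(min(n, M) + 1):
                direct = stats.hypergeom.sf(k - 1, N, M, n) < alpha
                assert (k >= kmin[n]) == direct, (N, M, n, k, alpha)


class TestSelectByBenchmark:
    def test_empty_candidates(self, star_net):
        sel, rem, tests = select_by_benchmark(
            star_net, GeneList("C", ()), GeneList("B", ("H",))
        )
        assert len(sel) == 0 and len(rem) == 0 and tests == []

    def test_benchmark_off_network_rejected(self, star_net):
        with pytest.raises(ParameterError):
            select_by_benchmark(
                star_net, GeneList("C", ("L1",)), GeneList("B", ("X", "Y"))
            )

    def test_isolated_candidate_never_selected(self, default_synthetic):
        _, net, module_map = default_synthetic
        bench = GeneList("B", tuple(sorted(module_map)[:40]))
        isolated = [
            g for g in net.node_list
            if net.link_degree[net.index_of(g)] == 0
        ]
        if not isolated:
            pytest.skip("fixture has no isolated gene")
        cand = GeneList("C", tuple(isolated[:3]))
        sel, rem, _ = select_by_benchmark(net, cand, bench, fdr_level=0.05)
        assert len(sel) == 0

    def test_module_candidates_selected_against_module_benchmark(self):
        # candidates inside a module dense with benchmark genes are picked
        hits = 0
        for seed in range(20):
            spec = ModularNetworkSpec(
                n_genes=400, n_modules=4, module_size=40, p_in=0.3,
                p_out=0.005, seed=seed,
            )
            net, mm = generate_network(spec)
            mod0 = sorted(g for g, m in mm.items() if m == 0)
            bench = GeneList("B", tuple(mod0[:30]))
            cand = GeneList("C", (mod0[35],))
            sel, _, _ = select_by_benchmark(net, cand, bench, fdr_level=0.05)
            hits += len(sel)
        assert hits / 20 > 0.9

    def test_q_values_not_below_p(self, default_synthetic):
        _, net, module_map = default_synthetic
        genes = sorted(module_map)
        bench = GeneList("B", tuple(genes[:40]))
        cand = GeneList("C", tuple(genes[40:90]))
        _, _, tests = select_by_benchmark(net, cand, bench)
        assert all(t.q >= t.p - 1e-12 for t in tests)


class TestPrioritize:
    def test_hub_ranked_before_isolated(self):
        net = PPINetwork(
            [("HUB", "B1"), ("HUB", "B2"), ("HUB", "B3")] +
            [(f"X{i}", f"Y{i}") for i in range(20)],
            nodes=["LONER"],
        )
        bench = GeneList("B", ("B1", "B2", "B3"))
        ranked = prioritize(net, GeneList("C", ("LONER", "HUB")), bench)
        assert [t.gene for t in ranked] == ["HUB", "LONER"]

    def test_all_isolated_sorted_lexicographically(self):
        net = PPINetwork([("A", "B")], nodes=["Z2", "Z1", "Z3"])
        ranked = prioritize(
            net, GeneList("C", ("Z2", "Z3", "Z1")), GeneList("B", ("A", "B"))
        )
        assert [t.gene for t in ranked] == ["Z1", "Z2", "Z3"]

    def test_ranking_is_permutation(self, default_synthetic):
        _, net, module_map = default_synthetic
        genes = sorted(module_map)
        cand = GeneList("C", tuple(genes[50:70]))
        ranked = prioritize(net, cand, GeneList("B", tuple(genes[:40])))
        assert sorted(t.gene for t in ranked) == sorted(cand.genes)
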