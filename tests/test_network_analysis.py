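"""Unit tests for hubs, network comparison and enrichment."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from cernaforge.cerna import CeRNANetwork
from cernaforge.network_analysis import (
    compare_hubs,
    compare_stage_edges,
    extract_subnetwork,
    find_hubs,
    hypergeom_set_enrichment,
    randomization_enrichment,
)


def make_net(competing, regulatory=(), stage="global"):
    g = nx.Graph()
    for u, v in competing:
        g.add_node(u, kind="rna", rna_class="mRNA")
        g.add_node(v, kind="rna", rna_class="mRNA")
        g.add_edge(u, v, edge_type="competing")
    for m, t in regulatory:
        g.add_node(m, kind="mirna", rna_class="miRNA")
        g.add_edge(m, t, edge_type="regulatory")
    return CeRNANetwork(graph=g, stage_label=stage)


def chain_net(n, stage="global"):
    # node i has degree 2 except the endpoints; add a high-degree center
    edges = [(f"n{i}", f"n{i+1}") for i in range(n - 1)]
    return make_net(edges, stage=stage)


class TestFindHubs:
    def test_distinct_degrees_top_two_of_twenty(self):
        edges = []
        for i in range(1, 20):  # n0 connects to all, n1 to many...
            edges.append(("n00", f"n{i:02d}"))
        for i in range(2, 12):
            edges.append(("n01", f"n{i:02d}"))
        net = make_net(edges)
        rep = find_hubs(net, fraction=0.10)
        assert len(net.rna_nodes) == 20
        assert rep.hub_set == {"n00", "n01"}

    def test_star_graph(self):
        net = make_net([("c", f"l{i}") for i in range(9)])
        rep = find_hubs(net, fraction=0.10)
        assert rep.hub_set == {"c"}

    def test_matches_bruteforce_sort_oracle(self, default_dataset):
        from cernaforge.pipeline import RunConfig, bundle_from_dataset, run_pipeline

        res = run_pipeline(bundle_from_dataset(default_dataset),
                           RunConfig(input_dir="x", seed=1, n_perm=200))
        net = res.network
        rep = find_hubs(net, fraction=0.10)
        deg = {n: sum(1 for e in net.competing_edges if n in e) for n in net.rna_nodes}
        ranked = sorted(deg, key=lambda n: (-deg[n], n))
        n_sel = math.ceil(0.10 * len(ranked))
        cutoff = deg[ranked[n_sel - 1]]
        oracle = {n for n in deg if deg[n] >= cutoff}
        assert rep.hub_set == oracle

    def test_mirna_nodes_excluded_from_degree(self):
        net = make_net([("a", "b")], regulatory=[("m1", "a"), ("m2", "a"), ("m3", "a")])
        rep = find_hubs(net, fraction=0.5)
        assert rep.degree["a"] == rep.degree["b"] == 1
        assert "m1" not in rep.degree.index

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_hubs(CeRNANetwork(graph=nx.Graph()))


class TestCompareHubs:
    def test_identical_and_disjoint(self):
        a = find_hubs(make_net([("a", "b")], stage="growth"), fraction=1.0)
        b = find_hubs(make_net([("a", "b")], stage="senescence"), fraction=1.0)
        common, gs, ss = compare_hubs(a, b)
        assert common == {"a", "b"} and gs == set() and ss == set()
        c = find_hubs(make_net([("x", "y")]), fraction=1.0)
        common, gs, ss = compare_hubs(a, c)
        assert common == set() and gs == {"a", "b"} and ss == {"x", "y"}

    def test_outputs_partition_both_hub_sets(self):
        a = find_hubs(make_net([("a", "b"), ("b", "c")]), fraction=1.0)
        b = find_hubs(make_net([("b", "c"), ("c", "d")]), fraction=1.0)
        common, gs, ss = compare_hubs(a, b)
        assert common | gs == a.hub_set and common | ss == b.hub_set
        assert not (common & gs) and not (common & ss) and not (gs & ss)


class TestExtractSubnetwork:
    def test_identity_on_full_node_set(self):
        net = make_net([("a", "b"), ("b", "c")], regulatory=[("m1", "a"), ("m1", "b")])
        sub = extract_subnetwork(net, net.rna_nodes)
        assert sub.competing_edges == net.competing_edges
        assert sub.regulatory_edges == net.regulatory_edges

    def test_no_internal_edges(self):
        net = make_net([("a", "b"), ("c", "d")])
        sub = extract_subnetwork(net, {"a", "c"})
        assert sub.competing_edges == set()


class TestRandomizationEnrichment:
    def test_annotated_equals_background(self):
        bg = {f"g{i}" for i in range(50)}
        q = {f"g{i}" for i in range(10)}
        res = randomization_enrichment(q, bg, bg, n_perm=200, seed=0)
        assert res.overlap == len(q)
        assert res.p_perm == 1.0

    def test_deterministic_given_seed(self):
        bg = {f"g{i}" for i in range(100)}
        q = {f"g{i}" for i in range(15)}
        ann = {f"g{i}" for i in range(5, 30)}
        r1 = randomization_enrichment(q, ann, bg, n_perm=500, seed=7)
        r2 = randomization_enrichment(q, ann, bg, n_perm=500, seed=7)
        assert r1.p_perm == r2.p_perm

    def test_agrees_with_hypergeometric_tail(self):
        rng = np.random.default_rng(0)
        bg = {f"g{i}" for i in range(300)}
        ann = set(rng.choice(sorted(bg), 60, replace=False))
        q = set(rng.choice(sorted(bg), 30, replace=False)) | set(sorted(ann)[:8])
        q = set(sorted(q)[:30])
        res = randomization_enrichment(q, ann, bg, n_perm=20_000, seed=1)
        exact = float(stats.hypergeom.sf(res.overlap - 1, 300, 60, 30))
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_perm - exact) <= 3 * se + 1 / 20_000

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            randomization_enrichment({"x"}, set(), {"a", "b", "c"}, n_perm=100)


def brute_force_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestHypergeomSetEnrichment:
    def test_bh_matches_bruteforce_oracle(self):
        bg = {f"g{i}" for i in range(1000)}
        queries = [(f"q{j}", set(list(sorted(bg))[j * 20:(j + 1) * 20])) for j in range(4)]
        ann = {"s": set(list(sorted(bg))[10:200])}
        out = hypergeom_set_enrichment(queries, ann, bg)
        assert out["fdr"].tolist() == pytest.approx(brute_force_bh(out["p_hyper"].tolist()))

    def test_bh_equalizing_example(self):
        # classic BH ladder: (0.01, 0.02, 0.03, 0.04) over m=4 all adjust to 0.04
        assert brute_force_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert adj.tolist() == pytest.approx([0.04] * 4)

    def test_single_set_fdr_equals_p(self):
        bg = {f"g{i}" for i in range(100)}
        out = hypergeom_set_enrichment([("q", set(list(sorted(bg))[:10]))],
                                       {"s": set(list(sorted(bg))[5:30])}, bg)
        assert out["fdr"].iloc[0] == pytest.approx(out["p_hyper"].iloc[0])

    def test_zero_overlap_not_significant(self):
        bg = {f"g{i}" for i in range(100)}
        out = hypergeom_set_enrichment([("q", set(list(sorted(bg))[:10]))],
                                       {"s": set(list(sorted(bg))[90:])}, bg)
        assert out["p_hyper"].iloc[0] > 0.3
        assert not out["significant"].iloc[0]

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            hypergeom_set_enrichment([("q", set())], {"s": set()}, set())


class TestCompareStageEdges:
    def test_identical_networks_no_stage_only(self):
        g = make_net([("a", "b"), ("b", "c")], stage="growth")
        s = make_net([("a", "b"), ("b", "c")], stage="senescence")
        common, go, so = compare_stage_edges(g, s, {"a", "b", "c"})
        assert len(common) == 2 and not go and not so

    def test_empty_focus_empty_outputs(self):
        g = make_net([("a", "b")], stage="growth")
        s = make_net([("b", "c")], stage="senescence")
        assert compare_stage_edges(g, s, set()) == (set(), set(), set())

    def test_partition_property(self):
        g = make_net([("a", "b"), ("b", "c"), ("c", "d")], stage="growth")
        s = make_net([("b", "c"), ("d", "e")], stage="senescence")
        focus = {"b", "c", "d"}
        common, go, so = compare_stage_edges(g, s, focus)
        ge = {e for e in g.competing_edges if e & focus}
        se = {e for e in s.competing_edges if e & focus}
        assert common | go == ge and common | so == se
        assert not (go & so) and not (common & go) and not (common & so)
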