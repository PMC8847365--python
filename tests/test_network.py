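import itertools

import networkx as nx
import numpy as np
import pytest

from lncquarry.expression import TargetAssignment
from lncquarry.models import GeneSet
from lncquarry.network import (
    build_network,
    cohesiveness,
    detect_modules,
    enrich,
    module_significance,
    overlap_score,
)


def clique_pair_graph():
    """Two 6-cliques joined by a single bridge edge."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(6)]
    b = [f"b{i}" for i in range(6)]
    for grp in (a, b):
        for u, v in itertools.combinations(grp, 2):
            g.add_edge(u, v, weight=1.0)
    g.add_edge("a0", "b0", weight=1.0)
    return g, frozenset(a), frozenset(b)


class TestBuildNetwork:
    def test_union_of_ppi_and_assignments(self):
        g = build_network([("m1", "m2", 1.0), ("m2", "m3", 0.5)],
                          [TargetAssignment("l1", "m1", "trans", r=0.99)])
        assert g.number_of_edges() == 3
        assert g.nodes["l1"]["kind"] == "lncRNA"
        assert g.nodes["m1"]["kind"] == "mRNA"

    def test_duplicate_edges_keep_max_weight(self):
        g = build_network([("m1", "m2", 0.4), ("m2", "m1", 0.9)], [])
        assert g["m1"]["m2"]["weight"] == 0.9

    def test_self_loops_dropped(self):
        g = build_network([("m1", "m1", 1.0), ("m1", "m2", 1.0)], [])
        assert g.number_of_edges() == 1


class TestCohesiveness:
    def test_isolated_triangle_without_penalty_is_one(self):
        g = build_network([("a", "b", 1.0), ("b", "c", 1.0),
                           ("a", "c", 1.0)], [])
        assert cohesiveness(g, {"a", "b", "c"}, penalty=0.0) == 1.0

    def test_triangle_with_penalty_two_is_one_third(self):
        g = build_network([("a", "b", 1.0), ("b", "c", 1.0),
                           ("a", "c", 1.0)], [])
        assert cohesiveness(g, {"a", "b", "c"}, penalty=2.0) == \
            pytest.approx(3 / (3 + 0 + 6))

    def test_single_node_with_external_edge_is_zero(self):
        g = build_network([("a", "b", 1.0)], [])
        assert cohesiveness(g, {"a"}, penalty=0.0) == 0.0

    def test_empty_set_rejected(self):
        g = build_network([("a", "b", 1.0)], [])
        with pytest.raises(ValueError):
            cohesiveness(g, set())

    def test_matches_hand_formula_on_all_small_subsets(self):
        rng = np.random.default_rng(40)
        g = nx.gnp_random_graph(12, 0.35, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        nodes = sorted(g.nodes)
        for size in (1, 2, 3):
            for subset in itertools.combinations(nodes, size):
                sset = set(subset)
                w_in = sum(d["weight"] for u, v, d in g.edges(data=True)
                           if u in sset and v in sset)
                w_bound = sum(d["weight"] for u, v, d in g.edges(data=True)
                              if (u in sset) != (v in sset))
                denom = w_in + w_bound + 2.0 * size
                expected = w_in / denom if denom else 0.0
                assert cohesiveness(g, sset, 2.0) == pytest.approx(expected)


class TestDetectModules:
    def test_two_cliques_isolated_as_two_modules(self):
        g, a, b = clique_pair_graph()
        modules = detect_modules(g, min_size=5, penalty=2.0)
        assert sorted(m.nodes for m in modules) == sorted([a, b])

    def test_small_groups_filtered_by_min_size(self):
        g = nx.Graph()
        for u, v in itertools.combinations("abcd", 2):
            g.add_edge(u, v, weight=1.0)
        assert detect_modules(g, min_size=5) == []

    def test_deterministic_across_runs(self):
        g, _, _ = clique_pair_graph()
        first = [m.nodes for m in detect_modules(g)]
        for _ in range(3):
            assert [m.nodes for m in detect_modules(g)] == first

    def test_empty_network_gives_no_modules(self):
        assert detect_modules(nx.Graph()) == []

    def test_overlap_score_definition(self):
        assert overlap_score(frozenset("abcd"), frozenset("cdef")) == \
            pytest.approx(4 / 16)


class TestModuleSignificance:
    def _planted(self, seed=50):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(40, 60, seed=int(seed))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        clique = [f"c{i}" for i in range(6)]
        for u, v in itertools.combinations(clique, 2):
            g.add_edge(u, v, weight=1.0)
        g.add_edge("c0", "n00", weight=1.0)
        return g, clique

    def test_planted_clique_is_significant(self):
        g, clique = self._planted()
        p = module_significance(g, clique, n_null=300, seed=1)
        assert p <= 0.01

    def test_p_value_never_below_add_one_bound(self):
        g, clique = self._planted()
        p = module_significance(g, clique, n_null=50, seed=2)
        assert p >= 1 / 51

    def test_random_module_from_rewired_graph_is_calibrated(self):
        g, _ = self._planted(seed=51)
        rng = np.random.default_rng(3)
        nodes = sorted(g.nodes)
        pvals = []
        for trial in range(40):
            module = list(rng.choice(nodes, size=5, replace=False))
            pvals.append(module_significance(g, module, n_null=60,
                                             seed=100 + trial))
        assert 0.25 <= float(np.median(pvals)) <= 1.0

    def test_unknown_module_node_rejected(self):
        g, _ = self._planted()
        with pytest.raises(ValueError):
            module_significance(g, ["ghost"], n_null=10, seed=0)


class TestEnrich:
    def test_full_overlap_closed_form(self):
        # N=10, K=5, n=5, k=5 -> p = 1 / C(10,5) = 1/252
        background = [f"g{i}" for i in range(10)]
        sets = [GeneSet("S", "d", frozenset(background[:5]))]
        df = enrich(background[:5], sets, background)
        assert df.loc[0, "p_value"] == pytest.approx(1 / 252)

    def test_zero_overlap_p_is_one(self):
        background = [f"g{i}" for i in range(10)]
        sets = [GeneSet("S", "d", frozenset(background[:5]))]
        df = enrich(background[5:], sets, background)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_equals_background_saturates(self):
        background = [f"g{i}" for i in range(10)]
        sets = [GeneSet("S", "d", frozenset(background[:4]))]
        df = enrich(background, sets, background)
        assert df.loc[0, "overlap"] == 4
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrich(["x"], [GeneSet("S", "d", frozenset("ab"))], ["a", "b"])

    def test_hypergeometric_matches_exact_enumeration(self):
        from math import comb
        rng = np.random.default_rng(60)
        for _ in range(50):
            n_bg = int(rng.integers(5, 21))
            background = [f"g{i}" for i in range(n_bg)]
            big_k = int(rng.integers(1, n_bg + 1))
            n_query = int(rng.integers(1, n_bg + 1))
            members = list(rng.choice(background, size=big_k, replace=False))
            query = list(rng.choice(background, size=n_query, replace=False))
            k = len(set(query) & set(members))
            df = enrich(query, [GeneSet("S", "d", frozenset(members))],
                        background)
            exact = sum(comb(big_k, j) * comb(n_bg - big_k, n_query - j)
                        for j in range(k, min(big_k, n_query) + 1)
                        ) / comb(n_bg, n_query)
            assert df.loc[0, "p_value"] == pytest.approx(exact, rel=1e-9)

    def test_bh_over_sets_matches_stepup(self):
        rng = np.random.default_rng(61)
        background = [f"g{i}" for i in range(30)]
        sets = []
        for i in range(8):
            size = int(rng.integers(3, 15))
            sets.append(GeneSet(f"S{i}", "d", frozenset(
                rng.choice(background, size=size, replace=False))))
        query = list(rng.choice(background, size=10, replace=False))
        df = enrich(query, sets, background)
        p = df["p_value"].values
        n = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            running = min(running, p[order[rank]] * n / (rank + 1))
            expected[order[rank]] = running
        assert np.allclose(df["q_value"].values, expected)


def test_planted_world_modules_detected_and_enriched(world):
    g = build_network(world.ppi_edges, [])
    modules = detect_modules(g, min_size=5, penalty=2.0)
    found = {frozenset(m.nodes) for m in modules}
    for planted in world.truth.modules:
        assert frozenset(planted) in found
    # planted module genes enrich their matching gene set at q < 0.1
    background = sorted({n for a, b, _ in world.ppi_edges for n in (a, b)})
    df = enrich(world.truth.modules[0], world.gene_sets, background)
    top = df.iloc[0]
    assert top["set_id"] == "SET_MODULE_1"
    assert top["significant"]
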