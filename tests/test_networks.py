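import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, hypergeom

from traitnet import networks


def assoc_frame(rows):
    return pd.DataFrame(rows, columns=["item_a", "item_b", "str_pos", "str_neg", "direction"])


class TestBuildNetwork:
    def test_single_pair_single_edge(self):
        table = assoc_frame([("a", "b", 5.0, 0.0, "positive")])
        g = networks.build_network(table, "positive", ["a", "b", "c"])
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["weight"] == 5.0

    def test_degree_matches_partner_count(self):
        rows = [("a", "b", 1, 0, "positive"), ("a", "c", 2, 0, "positive"),
                ("b", "c", 0, 3, "negative"), ("a", "d", 4, 0, "positive")]
        table = assoc_frame(rows)
        g = networks.build_network(table, "positive", list("abcd"))
        assert g.degree["a"] == 3
        assert "c" in g and g.degree["c"] == 1

    def test_subset_restricts_nodes(self):
        table = assoc_frame([("a", "b", 1, 0, "positive"), ("a", "z", 1, 0, "positive")])
        g = networks.build_network(table, "positive", ["a", "b"])
        assert "z" not in g


class TestCommunities:
    def two_cliques(self):
        g = nx.Graph()
        for grp in ("abcd", "efgh"):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v, weight=1.0)
        g.add_edge("a", "e", weight=1.0)
        return g

    def test_two_cliques_recovered_and_optimal(self):
        g = self.two_cliques()
        comms, q = networks.cnm_communities(g)
        bf, bq = networks.brute_force_max_modularity(g)
        assert comms == bf
        assert q == pytest.approx(bq)
        assert comms == [frozenset("abcd"), frozenset("efgh")]

    def test_single_edge_single_community_q_zero(self):
        g = nx.Graph([("a", "b")])
        q = nx.algorithms.community.modularity(g, [{"a", "b"}])
        assert q == pytest.approx(0.0)

    def test_dominates_random_partitions(self):
        g = self.two_cliques()
        _, q = networks.cnm_communities(g)
        rng = np.random.default_rng(0)
        nodes = list(g.nodes)
        for _ in range(1000):
            labels = rng.integers(0, 3, size=len(nodes))
            parts = [
                {n for n, l in zip(nodes, labels) if l == k}
                for k in range(3)
            ]
            parts = [p for p in parts if p]
            assert q >= nx.algorithms.community.modularity(g, parts, weight="weight") - 1e-12

    def test_node_order_invariance(self):
        g1 = self.two_cliques()
        g2 = nx.Graph()
        for u, v, d in reversed(list(g1.edges(data=True))):
            g2.add_edge(v, u, **d)
        assert networks.cnm_communities(g1)[0] == networks.cnm_communities(g2)[0]

    def test_disconnected_components(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        comms, _ = networks.cnm_communities(g)
        assert frozenset("ab") in comms and frozenset("cd") in comms


class TestFisher:
    def test_matches_hypergeometric_enumeration_small_tables(self):
        """Two-sided Fisher p equals direct hypergeometric enumeration, n <= 12."""
        for n in range(1, 13):
            for r1 in range(n + 1):          # row-1 margin
                for c1 in range(n + 1):      # col-1 margin
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    for a in range(lo, hi + 1):
                        table = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                        p_obs = hypergeom.pmf(a, n, r1, c1)
                        enum = sum(
                            hypergeom.pmf(k, n, r1, c1)
                            for k in range(lo, hi + 1)
                            if hypergeom.pmf(k, n, r1, c1) <= p_obs * (1 + 1e-9)
                        )
                        _, p = fisher_exact(table, alternative="two-sided")
                        assert p == pytest.approx(min(enum, 1.0), abs=1e-9)

    def test_perfect_overlap_minimal_p(self):
        g = nx.Graph()
        for e in [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f")]:
            g.add_edge(*e, weight=1.0)
        cats = {"a": "X", "b": "X", "c": "X", "d": "Y", "e": "Y", "f": "Y"}
        comms = [frozenset("abc"), frozenset("def")]
        res = networks.community_enrichment(g, comms, cats)
        perfect = res[(res.community == 0) & (res.category == "X")].iloc[0]
        assert perfect["p"] == res[res.community == 0]["p"].min()
        assert perfect["p"] == pytest.approx(fisher_exact([[3, 0], [0, 3]])[1])

    def test_uncategorized_node_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            networks.community_enrichment(g, [frozenset("ab")], {"a": "X"})


class TestSignEnrichment:
    def test_balanced_split_not_enriched(self):
        rows = []
        for k in range(4):
            rows.append((f"c{k}", f"c{k+10}", 1, 0, "positive" if k % 2 else "negative"))
            rows.append((f"o{k}", f"o{k+10}", 1, 0, "positive" if k % 2 else "negative"))
        table = assoc_frame(rows)
        carbon = [f"c{k}" for k in range(20)]
        res = networks.sign_enrichment(table, carbon)
        assert res["p"] == pytest.approx(1.0)

    def test_skewed_split_detected(self):
        rows = [(f"c{k}", f"c{k+30}", 1, 0, "positive") for k in range(12)]
        rows += [(f"o{k}", f"o{k+30}", 1, 0, "negative") for k in range(12)]
        table = assoc_frame(rows)
        res = networks.sign_enrichment(table, [f"c{k}" for k in range(60)])
        assert res["p"] < 0.001
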