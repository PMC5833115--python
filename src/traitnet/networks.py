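"""Signed association networks over carbon traits: communities and enrichment.

Nodes are carbon-utilization traits with at least one significant association
of the requested sign; edges are the significant same-sign pairs, weighted by
association strength.  Communities come from greedy modularity maximization
(Clauset-Newman-Moore agglomeration) and category enrichment within each
community is tested with two-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy.stats import fisher_exact

from .associations import NEGATIVE, POSITIVE, significant_pairs

log = logging.getLogger("traitnet")


def build_network(
    assoc: pd.DataFrame, sign: str, trait_subset, category_map: dict | None = None
) -> nx.Graph:
    """Graph of significant ``sign`` associations among ``trait_subset``."""
    if sign not in (POSITIVE, NEGATIVE):
        raise ValueError("sign must be 'positive' or 'negative'")
    subset = set(trait_subset)
    if not subset:
        raise ValueError("trait subset is empty")
    g = nx.Graph(sign=sign)
    strength_col = "str_pos" if sign == POSITIVE else "str_neg"
    for row in significant_pairs(assoc, sign).itertuples():
        if row.item_a in subset and row.item_b in subset:
            g.add_edge(row.item_a, row.item_b, weight=float(getattr(row, strength_col)))
    if g.number_of_edges() == 0:
        log.warning("no significant %s associations within the trait subset", sign)
    if category_map:
        nx.set_node_attributes(
            g, {n: category_map.get(n, "uncategorized") for n in g}, "category"
        )
    return g


def cnm_communities(g: nx.Graph, weighted: bool = True):
    """Greedy modularity (CNM) partition and its modularity Q.

    Ties during agglomeration are resolved deterministically; the returned
    communities are sorted by their lexicographically smallest node so the
    partition is invariant to node insertion order.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    weight = "weight" if weighted else None
    comms = greedy_modularity_communities(g, weight=weight)
    comms = sorted((frozenset(c) for c in comms), key=lambda c: sorted(c))
    q = modularity(g, comms, weight=weight)
    return comms, q


def community_enrichment(g: nx.Graph, communities, category_map: dict) -> pd.DataFrame:
    """Two-sided Fisher exact test of each (community, category) 2x2 table.

    Table margins run over the network's nodes: membership in the community
    versus membership in the category.
    """
    nodes = list(g.nodes)
    missing = [n for n in nodes if n not in category_map]
    if missing:
        raise ValueError(f"uncategorized node(s): {missing[:5]}")
    cats = sorted({category_map[n] for n in nodes})
    rows = []
    for ci, comm in enumerate(communities):
        for cat in cats:
            in_cat = {n for n in nodes if category_map[n] == cat}
            if not in_cat:
                log.info("category %r absent from network; skipped", cat)
                continue
            a = len(comm & in_cat)
            b = len(comm) - a
            c = len(in_cat) - a
            d = len(nodes) - a - b - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({
                "community": ci, "category": cat,
                "in_comm_in_cat": a, "in_comm_out_cat": b,
                "out_comm_in_cat": c, "out_comm_out_cat": d,
                "odds_ratio": odds, "p": p,
            })
    return pd.DataFrame(rows)


def sign_enrichment(assoc: pd.DataFrame, carbon_traits) -> dict:
    """Are carbon-carbon pairs enriched for positive (vs negative) calls?

    2x2 table: {carbon-carbon pairs, all other significant pairs} x
    {positive, negative}; two-sided Fisher exact test.
    """
    carbon = set(carbon_traits)
    sig = significant_pairs(assoc)
    is_carbon = sig.apply(lambda r: r["item_a"] in carbon and r["item_b"] in carbon, axis=1)
    if len(sig) == 0:
        raise ValueError("no significant associations")
    pos = sig["direction"] == POSITIVE
    table = [
        [int((is_carbon & pos).sum()), int((is_carbon & ~pos).sum())],
        [int((~is_carbon & pos).sum()), int((~is_carbon & ~pos).sum())],
    ]
    odds, p = fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": odds, "p": p}


def export_edge_list(g: nx.Graph, communities, path) -> None:
    """Edge-list TSV with weights and community ids of the endpoints."""
    member = {}
    for ci, comm in enumerate(communities):
        for n in comm:
            member[n] = ci
    rows = [
        {"a": a, "b": b, "weight": d.get("weight", 1.0),
         "community_a": member.get(a, -1), "community_b": member.get(b, -1)}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def brute_force_max_modularity(g: nx.Graph, weighted: bool = True):
    """Exhaustive maximum-modularity partition (testing oracle; <= ~10 nodes)."""
    nodes = list(g.nodes)
    if len(nodes) > 10:
        raise ValueError("brute force limited to 10 nodes")
    weight = "weight" if weighted else None

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield part + [[first]]

    best_q, best = -1.0, None
    for part in partitions(nodes):
        q = modularity(g, [set(p) for p in part], weight=weight)
        if q > best_q:
            best_q, best = q, part
    return sorted((frozenset(p) for p in best), key=lambda c: sorted(c)), best_q
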