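"""Self-contained calibration checks of the whole pipeline.

Each function generates its own inputs (enumeration classes, synthetic
matrices, Yule trees), runs the corresponding pipeline stage, and returns the
measured quantity: null-model exactness against exhaustive enumeration,
type-I error and power of the association calls, calibration of the D
statistic, variance-partition algebra, community detection against brute
force, and the exact-test/multiple-testing primitives against enumeration
oracles.  The problem sizes are chosen so the full suite runs in minutes on
one core; the methods note records them.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from . import associations, null_model, phylo_signal, simulate, varpart
from .networks import brute_force_max_modularity, cnm_communities


# ---------------------------------------------------------------- null model

def margin_class_3x3():
    """All 3x3 binary matrices with row sums (2,1,1) and column sums (2,1,1)."""
    members = []
    for bits in itertools.product([0, 1], repeat=9):
        m = np.array(bits, dtype=np.int8).reshape(3, 3)
        if (m.sum(1) == [2, 1, 1]).all() and (m.sum(0) == [2, 1, 1]).all():
            members.append(m)
    return members


def swap_margin_violations(seed: int = 0, n_matrices: int = 50, n_swaps: int = 1000):
    """Count replicates whose row or column sums differ from the input's."""
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_matrices):
        m = (rng.random((50, 20)) < rng.uniform(0.2, 0.6)).astype(np.int8)
        out = null_model.checkerboard_swap(m, n_swaps, rng)
        if not ((out.sum(0) == m.sum(0)).all() and (out.sum(1) == m.sum(1)).all()):
            bad += 1
    return bad, n_matrices


def enumeration_agreement(seed: int = 0, n_perm: int = 10_000, n_swaps: int = 50,
                          n_ensembles: int = 25):
    """Max relative error of ensemble pair-count means vs exhaustive enumeration.

    A single 10,000-permutation ensemble carries ~2% Monte-Carlo noise on the
    smallest pair mean of this class, which would swamp a 1% bias check, so
    the ensemble-mean measurement is averaged over ``n_ensembles``
    independent ensembles; any chain bias survives averaging, sampling noise
    does not.
    """
    members = margin_class_3x3()
    pairs = [(0, 1), (0, 2), (1, 2)]
    enum_mean = np.array(
        [[(m[:, a] * m[:, b]).sum() for a, b in pairs] for m in members]
    ).mean(0)
    acc = np.zeros(len(pairs))
    for r in range(n_ensembles):
        ens = null_model.build_ensemble(members[0], pairs, n_perm=n_perm,
                                        n_swaps=n_swaps, seed=seed + r)
        acc += ens.mean_pos
    avg = acc / n_ensembles
    return float(np.max(np.abs(avg - enum_mean) / enum_mean))


# ------------------------------------------------------- association calls

def type_one_error(seed: int = 0, n_seeds: int = 20, n_species: int = 500,
                   n_traits: int = 20, n_perm: int = 1000):
    """Fraction of pairs called significant on independent margin-matched traits."""
    rng = np.random.default_rng(seed)
    called = total = 0
    for _ in range(n_seeds):
        p = rng.uniform(0.2, 0.8, n_traits)
        x = (rng.random((n_species, n_traits)) < p).astype(np.int8)
        frame = pd.DataFrame(x, columns=[f"t{j:02d}" for j in range(n_traits)])
        table = associations.associate_all_traits(
            frame, n_perm=n_perm, n_swaps=null_model.recommended_swaps(x),
            seed=int(rng.integers(2**31 - 1)))
        called += int((table.direction != "none").sum())
        total += len(table)
    return called / total


def planted_recovery(seed: int = 0, n_seeds: int = 10, n_species: int = 500,
                     n_traits: int = 20, n_perm: int = 4000):
    """Power for planted module pairs (positive) and exclusion pairs (negative).

    One 4-trait module with an e^2 odds boost and four exclusion pairs per
    dataset; returns (positive recovery fraction, negative recovery fraction,
    worst per-dataset module recovery).
    """
    rng = np.random.default_rng(seed)
    hit_p = tot_p = hit_n = tot_n = 0
    worst_module = 1.0
    for k in range(n_seeds):
        truth = simulate.default_truth(
            n_traits, seed=int(rng.integers(2**31 - 1)), n_modules=1,
            module_size=4, module_boost=2.0, n_negative_pairs=4,
            negative_strength=-2.0)
        x = simulate.simulate_binary_traits(
            n_species, truth, seed=int(rng.integers(2**31 - 1)))
        frame = pd.DataFrame(x, columns=[f"t{j:02d}" for j in range(n_traits)])
        table = associations.associate_all_traits(
            frame, n_perm=n_perm, n_swaps=null_model.recommended_swaps(x),
            seed=int(rng.integers(2**31 - 1)))
        pos = {tuple(sorted(v)) for v in
               table[table.direction == "positive"][["item_a", "item_b"]].to_numpy()}
        neg = {tuple(sorted(v)) for v in
               table[table.direction == "negative"][["item_a", "item_b"]].to_numpy()}
        key = lambda i, j: tuple(sorted((f"t{i:02d}", f"t{j:02d}")))
        mod_hits = sum(key(i, j) in pos for i, j in truth.module_pairs())
        worst_module = min(worst_module, mod_hits / len(truth.module_pairs()))
        hit_p += mod_hits
        tot_p += len(truth.module_pairs())
        hit_n += sum(key(i, j) in neg for i, j in truth.negative_pairs)
        tot_n += len(truth.negative_pairs)
    return hit_p / tot_p, hit_n / tot_n, worst_module


# ------------------------------------------------------------- D statistic

def d_calibration(seed: int = 0, n_tips: int = 200, n_traits: int = 200,
                  n_sim: int = 200):
    """Mean D over threshold-Brownian traits and over tip-shuffled traits."""
    import dendropy

    nwk, _ = simulate.simulate_tree_and_traits(n_tips, [0.5], ["brownian"], seed=seed)
    idx = phylo_signal.TreeIndex.from_tree(
        dendropy.Tree.get(data=nwk, schema="newick"))
    rng = np.random.default_rng(seed + 1)
    d_brown, d_rand = [], []
    for k in range(n_traits):
        prev = int(rng.integers(int(0.2 * n_tips), int(0.8 * n_tips)))
        states = phylo_signal.brownian_threshold_states(idx, prev, rng)[:, 0]
        res = phylo_signal.d_statistic(idx, states, n_sim=n_sim,
                                       seed=int(rng.integers(2**31 - 1)))
        d_brown.append(res.D)
        res2 = phylo_signal.d_statistic(idx, rng.permutation(states), n_sim=n_sim,
                                        seed=int(rng.integers(2**31 - 1)))
        d_rand.append(res2.D)
    return float(np.mean(d_brown)), float(np.mean(d_rand))


# ------------------------------------------------------ variance partition

def varpart_checks(seed: int = 0, n: int = 1000):
    """(inclusion-exclusion error, max |shared| under orthogonality, bio gap).

    Orthogonal predictor blocks with a response driven by the biology block
    alone: shared fractions should vanish and unique(bio) should equal the
    total explained fraction.  The response carries observation noise — the
    Ezekiel adjustment assumes it, and a noise-free response would push the
    chance-level R^2 of the inactive blocks deterministically negative.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, 9))
    # center before QR so the blocks stay orthogonal after mean removal
    Q, _ = np.linalg.qr(raw - raw.mean(0))
    Xp, Xb, Xe = Q[:, :3], Q[:, 3:6], Q[:, 6:9]
    signal = Xb @ rng.normal(size=(3, 8))
    Y = signal + 0.3 * np.linalg.norm(signal) / np.sqrt(signal.size) * rng.normal(size=(n, 8))
    res = varpart.partition3(Y, Xp, Xb, Xe)
    parts = (res.phy + res.bio + res.env + res.phy_bio + res.phy_env
             + res.bio_env + res.phy_bio_env)
    incl_excl_err = abs(parts - res.total)
    max_shared = max(abs(res.phy_bio), abs(res.phy_env), abs(res.bio_env),
                     abs(res.phy_bio_env))
    bio_gap = abs(res.bio - res.total)
    return float(incl_excl_err), float(max_shared), float(bio_gap)


# ---------------------------------------------------- community detection

def cnm_test_graphs():
    """Small weighted graphs (<= 8 nodes) for exhaustive community checks."""
    graphs = []
    g = nx.Graph()
    for grp in ("abcd", "efgh"):
        for i, u in enumerate(grp):
            for v in grp[i + 1:]:
                g.add_edge(u, v, weight=1.0)
    g.add_edge("a", "e", weight=1.0)
    graphs.append(("two 4-cliques + bridge", g))
    g = nx.Graph()
    for grp in ("abc", "def"):
        for i, u in enumerate(grp):
            for v in grp[i + 1:]:
                g.add_edge(u, v, weight=2.0)
    g.add_edge("c", "d", weight=0.5)
    graphs.append(("two weighted triangles", g))
    graphs.append(("complete K5", nx.complete_graph(5)))
    graphs.append(("barbell triangles", nx.barbell_graph(3, 0)))
    g = nx.Graph()
    for sq in (list("abcd"), list("efgh")):
        for i in range(4):
            g.add_edge(sq[i], sq[(i + 1) % 4])
    g.add_edge("a", "e")
    graphs.append(("two squares + bridge", g))
    graphs.append(("star", nx.star_graph(5)))
    g = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
    graphs.append(("three components", g))
    return graphs


def cnm_matches_brute_force():
    """Fraction of test graphs where greedy modularity attains the exact optimum."""
    hits = names = 0
    failures = []
    for name, g in cnm_test_graphs():
        weighted = any("weight" in d for _, _, d in g.edges(data=True))
        _, q = cnm_communities(g, weighted=weighted)
        _, bq = brute_force_max_modularity(g, weighted=weighted)
        names += 1
        if abs(q - bq) < 1e-9:
            hits += 1
        else:
            failures.append(name)
    return hits / names, failures


# ------------------------------------------------------------- exact tests

def fisher_enumeration_error(max_n: int = 12):
    """Max |Fisher p - hypergeometric enumeration| over all 2x2 tables, n <= max_n."""
    worst = 0.0
    for n in range(1, max_n + 1):
        for r1 in range(n + 1):
            for c1 in range(n + 1):
                lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
                for a in range(lo, hi + 1):
                    enum = min(1.0, sum(p for p in pmf.values()
                                        if p <= pmf[a] * (1 + 1e-9)))
                    table = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                    _, p = fisher_exact(table, alternative="two-sided")
                    worst = max(worst, abs(p - enum))
    return worst


def bh_hand_check():
    """Max deviation of the BH adjustment from hand-computed step-up values."""
    cases = [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.05], [0.05]),
        # step-up: 0.04*4/3 = 0.0533 caps the 0.03*4/2 = 0.06 candidate
        ([0.001, 0.5, 0.04, 0.03], [0.004, 0.5, 0.16 / 3, 0.16 / 3]),
        ([1.0, 1.0], [1.0, 1.0]),
    ]
    worst = 0.0
    for p, expected in cases:
        q = associations.bh_adjust(p)
        worst = max(worst, float(np.max(np.abs(q - np.asarray(expected)))))
    return worst
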