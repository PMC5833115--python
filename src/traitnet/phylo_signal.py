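"""Phylogenetic signal of binary traits: the D dispersion statistic.

For a binary trait on a rooted tree, tip states are averaged up the tree
(each node's value is the unweighted mean of its daughters') and the observed
dispersion d_obs is the sum over internal nodes of absolute differences
between daughter values.  D scales d_obs between two nulls,

    D = (d_obs - mean d_brownian) / (mean d_random - mean d_brownian),

so that D is approximately 1 when states are randomly shuffled across tips and
approximately 0 when they arise by thresholding a Brownian-motion trait at the
observed prevalence.  D < 0 indicates stronger-than-Brownian clumping, D > 1
over-dispersion.  Branch lengths enter only the Brownian simulation; the nodal
averaging is topology-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .data_io import normalize_label

log = logging.getLogger("traitnet")


@dataclass
class TreeIndex:
    """Array form of a rooted tree for vectorized traversals.

    Nodes are numbered in postorder (tips first occurrence included); tips
    occupy the ids listed in ``tip_ids``.
    """

    n_nodes: int
    tip_ids: np.ndarray            # node id per tip
    tip_labels: list[str]
    postorder_internal: list[tuple[int, list[int]]]   # (node id, child ids)
    preorder: list[tuple[int, int, float]]            # (node id, parent id, edge length); root first with parent -1

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TreeIndex":
        ids: dict = {}
        for node in tree.postorder_node_iter():
            ids[node] = len(ids)
        tip_ids, tip_labels = [], []
        post_internal = []
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if kids:
                post_internal.append((ids[node], [ids[c] for c in kids]))
            else:
                tip_ids.append(ids[node])
                tip_labels.append(normalize_label(node.taxon.label))
        pre = []
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            el = node.edge.length if node.edge.length is not None else 0.0
            pre.append((ids[node], ids[parent] if parent is not None else -1, float(el)))
        return cls(
            n_nodes=len(ids),
            tip_ids=np.asarray(tip_ids),
            tip_labels=tip_labels,
            postorder_internal=post_internal,
            preorder=pre,
        )


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex.from_tree(tree)


def _d_values(idx: TreeIndex, tip_states: np.ndarray) -> np.ndarray:
    """Sister-difference sums for a batch of state vectors.

    ``tip_states`` has shape (n_tips, n_rep); returns a length-n_rep vector.
    At a polytomy the contribution is the mean over all daughter pairs of
    absolute value differences, keeping scaling comparable to binary nodes.
    """
    n_rep = tip_states.shape[1]
    vals = np.zeros((idx.n_nodes, n_rep))
    vals[idx.tip_ids] = tip_states
    d = np.zeros(n_rep)
    for node, kids in idx.postorder_internal:
        kv = vals[kids]
        vals[node] = kv.mean(axis=0)
        if len(kids) == 1:  # unifurcation: nothing to contrast
            continue
        if len(kids) == 2:
            d += np.abs(kv[0] - kv[1])
        else:
            pairs = list(combinations(range(len(kids)), 2))
            acc = np.zeros(n_rep)
            for i, j in pairs:
                acc += np.abs(kv[i] - kv[j])
            d += acc / len(pairs)
    return d


def sum_sister_differences(tree, tip_states) -> float:
    """Observed d for one trait: states keyed by (normalized) tip label."""
    idx = _as_index(tree)
    states = _states_vector(idx, tip_states)
    return float(_d_values(idx, states[:, None])[0])


def _states_vector(idx: TreeIndex, tip_states) -> np.ndarray:
    if isinstance(tip_states, pd.Series):
        tip_states = {normalize_label(k): v for k, v in tip_states.items()}
    if isinstance(tip_states, dict):
        missing = [t for t in idx.tip_labels if t not in tip_states]
        if missing:
            raise ValueError(f"tip(s) without a state: {missing[:5]}")
        arr = np.asarray([tip_states[t] for t in idx.tip_labels], dtype=float)
    else:
        arr = np.asarray(tip_states, dtype=float)
        if arr.shape[0] != len(idx.tip_labels):
            raise ValueError("state vector length does not match tip count")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("tip states must be binary")
    return arr


def brownian_threshold_states(
    tree, n_ones: int, rng: np.random.Generator, n_rep: int = 1
) -> np.ndarray:
    """Binary tip states from thresholded Brownian evolution.

    A continuous trait evolves from the root with increments
    Normal(0, branch length); per replicate, the ``n_ones`` tips with the
    largest values are scored 1, reproducing the observed prevalence exactly.
    Returns an (n_tips, n_rep) array in ``tip_labels`` order.
    """
    idx = _as_index(tree)
    n_tips = len(idx.tip_labels)
    if not (0 < n_ones < n_tips):
        raise ValueError("prevalence must leave both states represented")
    vals = np.zeros((idx.n_nodes, n_rep))
    for node, parent, el in idx.preorder:
        if parent < 0:
            continue
        if el < 0:
            raise ValueError("branch lengths must be non-negative")
        vals[node] = vals[parent] + rng.normal(0.0, np.sqrt(el) if el > 0 else 0.0, size=n_rep)
    tipvals = vals[idx.tip_ids]
    order = np.argsort(-tipvals, axis=0, kind="stable")
    states = np.zeros((n_tips, n_rep))
    np.put_along_axis(states, order[:n_ones], 1.0, axis=0)
    return states


def _two_sided_p(null: np.ndarray, obs: float) -> float:
    n = len(null)
    lo = (1 + np.sum(null <= obs)) / (n + 1)
    hi = (1 + np.sum(null >= obs)) / (n + 1)
    return min(1.0, 2 * min(lo, hi))


@dataclass
class DResult:
    trait_id: str
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_vs_random: float
    p_vs_brownian: float
    n_sim: int
    n_tips: int
    prevalence: int


def d_statistic(
    tree, tip_states, n_sim: int = 1000, seed: int = 0, trait_id: str = ""
) -> DResult:
    """D with shuffle and threshold-Brownian nulls for one binary trait."""
    idx = _as_index(tree)
    states = _states_vector(idx, tip_states)
    n_tips = len(states)
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    k = int(states.sum())
    if k in (0, n_tips):
        raise ValueError("trait is constant on the tree's tips; D undefined")
    rng = np.random.default_rng(seed)
    d_obs = float(_d_values(idx, states[:, None])[0])
    shuffled = np.empty((n_tips, n_sim))
    for r in range(n_sim):
        shuffled[:, r] = rng.permutation(states)
    d_rand = _d_values(idx, shuffled)
    d_brown = _d_values(idx, brownian_threshold_states(idx, k, rng, n_rep=n_sim))
    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    if mean_r == mean_b:
        raise ValueError("degenerate nulls: random and Brownian means coincide")
    return DResult(
        trait_id=trait_id,
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=(d_obs - mean_b) / (mean_r - mean_b),
        p_vs_random=_two_sided_p(d_rand, d_obs),
        p_vs_brownian=_two_sided_p(d_brown, d_obs),
        n_sim=n_sim,
        n_tips=n_tips,
        prevalence=k,
    )


def d_for_matrix(
    tree: dendropy.Tree, m: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-trait D over a binary matrix; species absent from the tree are dropped.

    Traits constant on the retained tips are skipped with a log note.
    """
    idx = TreeIndex.from_tree(tree)
    species = pd.Index([normalize_label(s) for s in m.index])
    keep = [t for t in idx.tip_labels if t in set(species)]
    dropped = len(idx.tip_labels) - len(keep)
    if dropped:
        log.info("%d tree tips lack trait data and were pruned", dropped)
    absent = len(m) - len(keep)
    if absent:
        log.info("%d species absent from the tree were dropped", absent)
    if len(keep) < 4:
        raise ValueError("fewer than 4 species shared between tree and matrix")
    tree2 = _prune_to(tree, keep)
    idx2 = TreeIndex.from_tree(tree2)
    rows = []
    lookup = pd.DataFrame(m.to_numpy(), index=species, columns=m.columns)
    rng = np.random.default_rng(seed)
    for trait in m.columns:
        s = lookup[trait].reindex(idx2.tip_labels)
        if s.nunique() < 2:
            log.info("trait %r constant on shared tips; skipped", trait)
            continue
        res = d_statistic(idx2, s.to_numpy(), n_sim=n_sim,
                          seed=int(rng.integers(2**31 - 1)), trait_id=str(trait))
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def _prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    t = tree.clone(depth=1)
    keep = set(labels)
    taxa = [tax for tax in t.taxon_namespace if normalize_label(tax.label) in keep]
    t.retain_taxa(taxa)
    return t
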