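"""Clustering of traits by similarity of their association profiles.

Each trait's profile is its row of the signed association-strength matrix:
+strength for significant positive partners, -strength for significant
negative partners, and 0 elsewhere (including self).  Traits are clustered by
Ward's method on Euclidean distances between profiles, and cluster support is
assessed by bootstrap resampling of the profile coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .associations import NEGATIVE, POSITIVE


def association_profiles(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Trait x trait signed-strength matrix from an association table.

    Significant positive pairs contribute +str_pos, significant negative pairs
    -str_neg; non-significant pairs and the diagonal are 0.
    """
    if traits is None:
        traits = sorted(set(table["item_a"]) | set(table["item_b"]))
    prof = pd.DataFrame(0.0, index=traits, columns=traits)
    for row in table.itertuples():
        if row.item_a not in prof.index or row.item_b not in prof.index:
            continue
        if row.direction == POSITIVE:
            v = row.str_pos
        elif row.direction == NEGATIVE:
            v = -row.str_neg
        else:
            continue
        prof.loc[row.item_a, row.item_b] = v
        prof.loc[row.item_b, row.item_a] = v
    return prof


def profile_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix between trait profiles (rows)."""
    if not profiles.index.equals(profiles.columns):
        raise ValueError("profiles must be aligned on one trait ordering")
    d = squareform(pdist(profiles.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def ward_cluster(dist: pd.DataFrame, method: str = "ward") -> np.ndarray:
    """Ward linkage (variance-minimizing, Ward.D2 convention) on a distance matrix.

    Returns a scipy linkage matrix; ``method`` may be switched to any scipy
    linkage method for sensitivity analysis.
    """
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(dist.to_numpy(), checks=False)
    return linkage(condensed, method=method)


def _node_tip_sets(Z: np.ndarray, labels) -> list[frozenset]:
    """Tip-label set under each internal node of a linkage matrix."""
    n = Z.shape[0] + 1
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + k] = s
        out.append(s)
    return out


def cluster_support(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "ward",
) -> pd.Series:
    """Bootstrap probability (BP) of each internal node of the Ward tree.

    Profile coordinates (columns) are resampled with replacement ``n_boot``
    times; each node's support is the fraction of bootstrap trees containing
    a node with the identical tip set.  The root always has support 1.
    Returned Series is keyed by frozensets of tip labels.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 traits for cluster support")
    labels = list(profiles.index)
    Z = ward_cluster(profile_distance(profiles), method=method)
    target = _node_tip_sets(Z, labels)
    hits = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    x = profiles.to_numpy()
    p = x.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        xb = x[:, cols]
        Zb = linkage(pdist(xb, metric="euclidean"), method=method)
        for s in _node_tip_sets(Zb, labels):
            if s in hits:
                hits[s] += 1
    bp = {s: hits[s] / n_boot for s in target}
    bp[frozenset(labels)] = 1.0  # whole-set node is always recovered
    return pd.Series(list(bp.values()), index=pd.Index(list(bp.keys()), dtype=object))


def cut_clusters(Z: np.ndarray, labels, n_clusters: int) -> pd.Series:
    """Flat cluster assignment from a linkage matrix."""
    assign = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(assign, index=labels, name="cluster")


def linkage_to_newick(Z: np.ndarray, labels, support: pd.Series | None = None) -> str:
    """Render a linkage matrix as a newick string, supports as node labels."""
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    newick: dict[int, str] = {i: str(labels[i]) for i in range(n)}
    tips: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        lab = ""
        tips[node] = tips[a] | tips[b]
        if support is not None and tips[node] in support.index:
            lab = f"{support[tips[node]]:.3f}"
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g}){lab}"
        heights[node] = h
    return newick[2 * n - 2] + ";"
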