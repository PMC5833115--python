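"""Variance partitioning of trait-pair co-occurrence among three predictor sets.

The response is the species x trait-pair indicator matrix (1 iff both traits
of the pair are present in the species).  Explained variance is the
redundancy-analysis R^2 (sum over response columns of regression sums of
squares over total sum of squares), Ezekiel-adjusted,

    R2_a = 1 - (1 - R2) (n - 1) / (n - p - 1),

and the unique/shared fractions of phylogeny (cophenetic principal
coordinates), biological properties (carbon-category utilization counts), and
isolation environments are obtained by inclusion-exclusion over the seven
predictor-set unions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from skbio.stats.ordination import pcoa

from .data_io import normalize_label

log = logging.getLogger("traitnet")


def build_response(m: pd.DataFrame) -> pd.DataFrame:
    """Species x trait-pair indicator: 1 iff both traits present, else 0."""
    x = m.to_numpy(dtype=int)
    cols, data = [], []
    for i, j in combinations(range(x.shape[1]), 2):
        cols.append(f"{m.columns[i]}&{m.columns[j]}")
        data.append(x[:, i] * x[:, j])
    return pd.DataFrame(np.column_stack(data), index=m.index, columns=cols)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def adjusted_r2(Y, X) -> float:
    """Ezekiel-adjusted redundancy R^2 of a multivariate linear fit.

    Rank-deficient predictor sets are handled by using the effective rank as
    the predictor count p (collinear columns carry no extra penalty).
    """
    Yc = _center(np.asarray(Y, dtype=float))
    Xc = _center(np.asarray(X, dtype=float))
    n = Yc.shape[0]
    sst = float((Yc**2).sum())
    if sst == 0:
        raise ValueError("response has no variance")
    beta, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    if rank < Xc.shape[1]:
        log.warning("predictor matrix rank-deficient (rank %d < %d columns)", rank, Xc.shape[1])
    fitted = Xc @ beta
    r2 = float((fitted**2).sum()) / sst
    p = rank
    if n - p - 1 <= 0:
        raise ValueError("too few species for the number of predictors")
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


def phylo_predictors(
    tree: dendropy.Tree, species, cum_eig: float = 0.95
) -> pd.DataFrame:
    """Principal coordinates of the tree's cophenetic (patristic) distances.

    Positive-eigenvalue axes are retained up to ``cum_eig`` cumulative
    eigenvalue mass, giving a compact Euclidean embedding of phylogeny
    usable as a predictor block.
    """
    pdm = tree.phylogenetic_distance_matrix()
    labels = {normalize_label(t.label): t for t in tree.taxon_namespace if t}
    wanted = [normalize_label(s) for s in species]
    missing = [s for s in wanted if s not in labels]
    if missing:
        raise ValueError(f"species not in tree: {missing[:5]}")
    n = len(wanted)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(labels[wanted[i]], labels[wanted[j]])
    ord_res = pcoa(d, number_of_dimensions=0)
    eig = ord_res.eigvals.to_numpy()
    pos = eig > 1e-10
    eig_pos = eig[pos]
    cum = np.cumsum(eig_pos) / eig_pos.sum()
    k = int(np.searchsorted(cum, cum_eig) + 1)
    axes = ord_res.samples.to_numpy()[:, : k]
    return pd.DataFrame(axes, index=list(species),
                        columns=[f"PCo{i+1}" for i in range(k)])


def biology_predictors(m: pd.DataFrame, category_map: dict) -> pd.DataFrame:
    """Per-species counts of utilized carbon sources per functional category."""
    cats = sorted(set(category_map.values()))
    out = pd.DataFrame(0, index=m.index, columns=cats)
    for trait, cat in category_map.items():
        if trait in m.columns:
            out[cat] += m[trait].astype(int)
    return out


@dataclass
class PartitionResult:
    """Unique/shared adjusted-R^2 fractions of three predictor sets."""

    phy: float          # unique to phylogeny
    bio: float          # unique to biological properties
    env: float          # unique to isolation environments
    phy_bio: float
    phy_env: float
    bio_env: float
    phy_bio_env: float
    total: float        # R2_a of all predictors together
    residual: float

    def as_series(self) -> pd.Series:
        return pd.Series({
            "unique_phylogeny": self.phy,
            "unique_biology": self.bio,
            "unique_environment": self.env,
            "shared_phy_bio": self.phy_bio,
            "shared_phy_env": self.phy_env,
            "shared_bio_env": self.bio_env,
            "shared_all": self.phy_bio_env,
            "total_explained": self.total,
            "residual": self.residual,
        })


def partition3(Y, X_phy, X_bio, X_env) -> PartitionResult:
    """Three-set variance partition by inclusion-exclusion of adjusted R^2.

    Individual fractions may be slightly negative (adjusted-R^2 artifact) and
    are reported as computed.
    """
    for X in (X_phy, X_bio, X_env):
        if np.asarray(X).shape[0] != np.asarray(Y).shape[0]:
            raise ValueError("all matrices must share the species ordering/length")
    Xp, Xb, Xe = (np.asarray(X, dtype=float) for X in (X_phy, X_bio, X_env))
    r = {
        "p": adjusted_r2(Y, Xp),
        "b": adjusted_r2(Y, Xb),
        "e": adjusted_r2(Y, Xe),
        "pb": adjusted_r2(Y, np.hstack([Xp, Xb])),
        "pe": adjusted_r2(Y, np.hstack([Xp, Xe])),
        "be": adjusted_r2(Y, np.hstack([Xb, Xe])),
        "pbe": adjusted_r2(Y, np.hstack([Xp, Xb, Xe])),
    }
    total = r["pbe"]
    phy = total - r["be"]
    bio = total - r["pe"]
    env = total - r["pb"]
    phy_bio = r["pe"] + r["be"] - total - r["e"]
    phy_env = r["pb"] + r["be"] - total - r["b"]
    bio_env = r["pb"] + r["pe"] - total - r["p"]
    three = total - phy - bio - env - phy_bio - phy_env - bio_env
    return PartitionResult(
        phy=phy, bio=bio, env=env,
        phy_bio=phy_bio, phy_env=phy_env, bio_env=bio_env,
        phy_bio_env=three, total=total, residual=1 - total,
    )
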