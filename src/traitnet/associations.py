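"""Positive/negative pairwise association calls against the swap-permutation null.

For a pair of binary columns the positive count is the number of species with
(1,1) and the negative count the number with (1,0) or (0,1).  Expected counts
are means over fixed-margin permutations; association strength is
|observed - expected|; significance is the one-sided empirical permutation
p-value (add-one corrected), Benjamini-Hochberg adjusted within each side's
family.  A Wilson interval on the exceedance proportion is carried along as a
stability diagnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .data_io import eligible_environments
from .null_model import (
    PermutationEnsemble,
    _pair_count_arrays,
    _swap_kernel,
    all_pairs,
    build_ensemble,
)

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


def pair_counts(m: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Observed (1,1) count and (1,0)+(0,1) count for columns ``a`` and ``b``."""
    if a == b:
        raise ValueError("a pair must consist of two distinct columns")
    pos, neg = _pair_count_arrays(np.asarray(m, dtype=np.int8),
                                  np.array([a]), np.array([b]))
    return int(pos[0]), int(neg[0])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _empirical_p(exceed: np.ndarray, n_perm: int) -> np.ndarray:
    return (1 + exceed) / (n_perm + 1)


def _assemble_table(
    labels_a, labels_b, ens: PermutationEnsemble, alpha: float, pool_sides: bool
) -> pd.DataFrame:
    p_pos = _empirical_p(ens.exceed_pos, ens.n_perm)
    p_neg = _empirical_p(ens.exceed_neg, ens.n_perm)
    if pool_sides:
        q = bh_adjust(np.concatenate([p_pos, p_neg]))
        q_pos, q_neg = q[: len(p_pos)], q[len(p_pos):]
    else:
        q_pos, q_neg = bh_adjust(p_pos), bh_adjust(p_neg)
    str_pos = np.abs(ens.pos_obs - ens.mean_pos)
    str_neg = np.abs(ens.neg_obs - ens.mean_neg)
    ci_pos = proportion_confint(ens.exceed_pos, ens.n_perm, method="wilson")
    ci_neg = proportion_confint(ens.exceed_neg, ens.n_perm, method="wilson")
    sig_pos = q_pos < alpha
    sig_neg = q_neg < alpha
    direction = np.where(
        sig_pos & ~sig_neg, POSITIVE,
        np.where(sig_neg & ~sig_pos, NEGATIVE,
                 np.where(sig_pos & sig_neg,
                          np.where(q_pos <= q_neg, POSITIVE, NEGATIVE),
                          NONE)),
    )
    # for non-significant pairs, report the side with the larger deviation
    reported = np.where(direction == POSITIVE, POSITIVE,
                        np.where(direction == NEGATIVE, NEGATIVE,
                                 np.where(str_pos >= str_neg, POSITIVE, NEGATIVE)))
    return pd.DataFrame({
        "item_a": labels_a,
        "item_b": labels_b,
        "positive_obs": ens.pos_obs,
        "negative_obs": ens.neg_obs,
        "pos_exp": ens.mean_pos,
        "neg_exp": ens.mean_neg,
        "str_pos": str_pos,
        "str_neg": str_neg,
        "p_pos": p_pos,
        "p_neg": p_neg,
        "q_pos": q_pos,
        "q_neg": q_neg,
        "ci_pos_low": ci_pos[0], "ci_pos_high": ci_pos[1],
        "ci_neg_low": ci_neg[0], "ci_neg_high": ci_neg[1],
        "direction": direction,
        "reported_side": reported,
    })


def association_test(ens: PermutationEnsemble, a: int, b: int, alpha: float = 0.05) -> pd.Series:
    """Single-pair association result (p-values unadjusted: family of one)."""
    k = ens.pair_index(a, b)
    sub = PermutationEnsemble(
        ia=ens.ia[[k]], ib=ens.ib[[k]], n_perm=ens.n_perm, n_swaps=ens.n_swaps,
        seed=ens.seed, pos_obs=ens.pos_obs[[k]], neg_obs=ens.neg_obs[[k]],
        sum_pos=ens.sum_pos[[k]], sum_neg=ens.sum_neg[[k]],
        exceed_pos=ens.exceed_pos[[k]], exceed_neg=ens.exceed_neg[[k]],
    )
    return _assemble_table([a], [b], sub, alpha, pool_sides=False).iloc[0]


def associate_all_traits(
    m: pd.DataFrame,
    n_perm: int = 10_000,
    n_swaps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pool_sides: bool = False,
) -> pd.DataFrame:
    """Association table over all unordered trait pairs of a binary matrix."""
    x = m.to_numpy(dtype=np.int8)
    pairs = all_pairs(x.shape[1])
    ens = build_ensemble(x, pairs, n_perm=n_perm, n_swaps=n_swaps, seed=seed)
    labels_a = [m.columns[i] for i, _ in pairs]
    labels_b = [m.columns[j] for _, j in pairs]
    return _assemble_table(labels_a, labels_b, ens, alpha, pool_sides)


def associate_trait_environment(
    m: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 10_000,
    n_swaps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pool_sides: bool = False,
    min_species: int = 4,
) -> pd.DataFrame:
    """Trait-environment association table.

    Only the trait matrix is permuted; environment columns stay fixed.  Only
    environments with at least ``min_species`` member species are tested.
    """
    if not m.index.equals(env.index):
        raise ValueError("trait and environment tables must share the species index")
    ok = eligible_environments(env, min_species)
    if not ok.any():
        raise ValueError("no environment has enough member species to test")
    env_use = env.loc[:, ok]
    x = m.to_numpy(dtype=np.int8)
    e = np.ascontiguousarray(env_use.to_numpy(dtype=np.int64))
    t_sum = x.sum(axis=0, dtype=np.int64)
    e_sum = e.sum(axis=0)

    def counts(mat):
        pos = mat.T.astype(np.int64) @ e               # traits x envs
        neg = t_sum[:, None] + e_sum[None, :] - 2 * pos
        return pos, neg

    pos_obs, neg_obs = counts(x)
    sum_pos = np.zeros_like(pos_obs, dtype=float)
    sum_neg = np.zeros_like(neg_obs, dtype=float)
    exc_pos = np.zeros_like(pos_obs)
    exc_neg = np.zeros_like(neg_obs)
    rng = np.random.default_rng(seed)
    kernel_seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    for r in range(n_perm):
        perm = x.copy()
        _swap_kernel(perm, n_swaps, n_swaps, int(kernel_seeds[r]))
        pos, neg = counts(perm)
        sum_pos += pos
        sum_neg += neg
        exc_pos += pos >= pos_obs
        exc_neg += neg >= neg_obs
    n_t, n_e = pos_obs.shape
    flat = PermutationEnsemble(
        ia=np.repeat(np.arange(n_t), n_e), ib=np.tile(np.arange(n_e), n_t),
        n_perm=n_perm, n_swaps=n_swaps, seed=seed,
        pos_obs=pos_obs.ravel(), neg_obs=neg_obs.ravel(),
        sum_pos=sum_pos.ravel(), sum_neg=sum_neg.ravel(),
        exceed_pos=exc_pos.ravel(), exceed_neg=exc_neg.ravel(),
    )
    labels_a = np.repeat(m.columns.to_numpy(), n_e)
    labels_b = np.tile(env_use.columns.to_numpy(), n_t)
    return _assemble_table(labels_a, labels_b, flat, alpha, pool_sides)


def significant_pairs(table: pd.DataFrame, direction: str | None = None) -> pd.DataFrame:
    """Rows called significant, optionally restricted to one direction."""
    sig = table[table["direction"] != NONE]
    if direction is not None:
        sig = sig[sig["direction"] == direction]
    return sig
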