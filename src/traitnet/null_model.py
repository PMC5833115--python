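"""Fixed-margin null model for binary matrices via checkerboard swaps.

A checkerboard swap picks a random 2x2 submatrix equal to [[1,0],[0,1]] or
[[0,1],[1,0]] and flips it, which preserves every row and column sum.  A
"permutation" of the observed matrix is the state of the swap chain after
``n_swaps`` attempted swaps started from the observed matrix (failed draws
hold in place, keeping the chain's stationary distribution uniform over the
margin class); an ensemble of such permutations gives the null distribution
of per-pair co-occurrence counts.

The ensemble stores streaming summaries only (null means of the positive and
negative pair counts plus exceedance tallies against supplied observed
counts), so memory is O(pairs), not O(n_perm x matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

log = logging.getLogger("traitnet")


@njit(cache=True)
def _swap_kernel(mat, n_swaps, max_attempts, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n_r, n_c = mat.shape
    done = 0
    attempts = 0
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(n_r)
        r2 = np.random.randint(n_r)
        c1 = np.random.randint(n_c)
        c2 = np.random.randint(n_c)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == d and b == c and a != b:
            mat[r1, c1] = b
            mat[r1, c2] = a
            mat[r2, c1] = d
            mat[r2, c2] = c
            done += 1
    return done


def checkerboard_swap(
    m: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    count_successful: bool = False,
    attempt_factor: int = 10,
) -> np.ndarray:
    """Return a margin-preserving randomization of a binary matrix.

    Parameters
    ----------
    m : ndarray
        Strictly binary matrix; not modified.
    n_swaps : int
        Number of swaps per permutation.  By default every draw counts and a
        draw that hits no checkerboard leaves the matrix in place, which
        keeps the chain symmetric and its stationary distribution uniform
        over the fixed-margin class.  With ``count_successful=True`` only
        successful flips count (failed draws are retried, up to
        ``attempt_factor * n_swaps`` attempts); that mixes faster on sparse
        matrices but weights matrices by their checkerboard count, so it is
        an option, not the default.
    rng : numpy Generator
        Source of randomness (a fresh integer seed is drawn per call).
    """
    x = np.ascontiguousarray(m, dtype=np.int8)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix must be strictly binary")
    out = x.copy()
    seed = int(rng.integers(0, 2**31 - 1))
    max_attempts = attempt_factor * n_swaps if count_successful else n_swaps
    done = _swap_kernel(out, n_swaps, max_attempts, seed)
    if done == 0:
        log.warning("no checkerboard submatrix found; matrix returned unchanged")
    elif done < n_swaps and count_successful:
        log.info("only %d/%d successful swaps within attempt budget", done, n_swaps)
    return out


def _pair_count_arrays(mat: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    """(1,1) and (1,0)+(0,1) counts for the column pairs (ia, ib)."""
    cross = mat.T.astype(np.int64) @ mat
    colsum = mat.sum(axis=0, dtype=np.int64)
    pos = cross[ia, ib]
    neg = colsum[ia] + colsum[ib] - 2 * pos
    return pos, neg


@dataclass
class PermutationEnsemble:
    """Streaming null summaries for a set of column pairs."""

    ia: np.ndarray              # first column index of each pair
    ib: np.ndarray
    n_perm: int
    n_swaps: int
    seed: int
    pos_obs: np.ndarray         # observed counts the tallies were scored against
    neg_obs: np.ndarray
    sum_pos: np.ndarray = field(repr=False)
    sum_neg: np.ndarray = field(repr=False)
    exceed_pos: np.ndarray = field(repr=False)  # #replicates with null pos >= obs pos
    exceed_neg: np.ndarray = field(repr=False)

    @property
    def mean_pos(self) -> np.ndarray:
        return self.sum_pos / self.n_perm

    @property
    def mean_neg(self) -> np.ndarray:
        return self.sum_neg / self.n_perm

    def pair_index(self, a: int, b: int) -> int:
        hit = np.nonzero(((self.ia == a) & (self.ib == b)) | ((self.ia == b) & (self.ib == a)))[0]
        if len(hit) == 0:
            raise KeyError(f"pair ({a}, {b}) not covered by the ensemble")
        return int(hit[0])


def build_ensemble(
    m: np.ndarray,
    pairs,
    n_perm: int = 10_000,
    n_swaps: int = 1000,
    seed: int = 0,
    count_successful: bool = False,
) -> PermutationEnsemble:
    """Score ``n_perm`` independent swap permutations of ``m`` for each pair.

    Each replicate restarts from the observed matrix and applies ``n_swaps``
    checkerboard swaps, then the (1,1) and (1,0)+(0,1) counts of every
    requested column pair are accumulated.  Exceedance tallies are counted
    against the observed matrix's own pair counts.  Fully reproducible from
    ``seed``.
    """
    x = np.ascontiguousarray(m, dtype=np.int8)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix must be strictly binary")
    if n_perm < 100:
        log.warning("n_perm=%d < 100: empirical p-values will be unstable", n_perm)
    ia = np.asarray([p[0] for p in pairs], dtype=np.int64)
    ib = np.asarray([p[1] for p in pairs], dtype=np.int64)
    if np.any(ia == ib):
        raise ValueError("a pair must consist of two distinct columns")
    pos_obs, neg_obs = _pair_count_arrays(x, ia, ib)
    sum_pos = np.zeros(len(ia), dtype=np.float64)
    sum_neg = np.zeros(len(ia), dtype=np.float64)
    exceed_pos = np.zeros(len(ia), dtype=np.int64)
    exceed_neg = np.zeros(len(ia), dtype=np.int64)
    rng = np.random.default_rng(seed)
    max_attempts = 10 * n_swaps if count_successful else n_swaps
    kernel_seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    for r in range(n_perm):
        perm = x.copy()
        _swap_kernel(perm, n_swaps, max_attempts, int(kernel_seeds[r]))
        pos, neg = _pair_count_arrays(perm, ia, ib)
        sum_pos += pos
        sum_neg += neg
        exceed_pos += pos >= pos_obs
        exceed_neg += neg >= neg_obs
    return PermutationEnsemble(
        ia=ia, ib=ib, n_perm=n_perm, n_swaps=n_swaps, seed=seed,
        pos_obs=pos_obs, neg_obs=neg_obs,
        sum_pos=sum_pos, sum_neg=sum_neg,
        exceed_pos=exceed_pos, exceed_neg=exceed_neg,
    )


def recommended_swaps(m: np.ndarray, factor: int = 5) -> int:
    """Attempted-swap count giving good mixing: ``factor`` times the 1-count.

    A swap chain must propose moves touching every 1 several times before the
    state decorrelates from the start; on the fully enumerable 3x3 margin
    class and on dense random matrices, means converge once attempts exceed
    a few multiples of the number of 1s (see the methods note).
    """
    return factor * int(np.asarray(m).sum())


def all_pairs(n_cols: int):
    """All unordered column pairs (i < j)."""
    return [(i, j) for i in range(n_cols) for j in range(i + 1, n_cols)]
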