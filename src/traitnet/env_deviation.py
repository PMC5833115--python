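"""Observed-vs-expected trait associations within isolation environments.

If the trait associations seen globally are driven by an environment, then
within that environment's member species the observed pair counts should match
the fixed-margin null of the member submatrix (deviation near 0).  Random
draws of species ignoring environment serve as the control: on structured data
they deviate.  The control runs through the same code path as a synthetic
"random" environment, differing only in how species are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associations import NEGATIVE, POSITIVE
from .null_model import build_ensemble, recommended_swaps

log = logging.getLogger("traitnet")

#: sample-size grid for the random-draw control
CONTROL_SIZES = (4, 11, 26, 47, 76, 147, 217)


@dataclass
class DeviationResult:
    environment_id: str
    direction: str          # positive or negative pairs evaluated
    n_species: int
    n_pairs: int
    mean_deviation: float   # mean over pairs of observed - null mean
    sd_deviation: float


def _pairs_by_direction(assoc: pd.DataFrame, columns, use_all: bool):
    name_to_i = {c: i for i, c in enumerate(columns)}
    out = {POSITIVE: [], NEGATIVE: []}
    for row in assoc.itertuples():
        if row.item_a not in name_to_i or row.item_b not in name_to_i:
            continue
        d = row.direction if not use_all else row.reported_side
        if d in out:
            out[d].append((name_to_i[row.item_a], name_to_i[row.item_b]))
    return out


def environment_deviation(
    m: pd.DataFrame,
    members,
    assoc: pd.DataFrame,
    environment_id: str = "",
    n_perm: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
    use_all_pairs: bool = False,
) -> list[DeviationResult]:
    """Mean observed-minus-expected pair count within one species subset.

    ``members`` is a boolean mask or index of species; ``assoc`` the global
    association table whose significant pairs are evaluated (all pairs with
    ``use_all_pairs``).  A fresh swap ensemble is built on the submatrix so
    the null preserves within-subset margins; by default the attempted-swap
    count scales with the submatrix's 1-count so small subsets still mix.  Pairs whose traits are
    constant within the subset still have well-defined counts and are kept;
    only directions with no evaluable pair are dropped.
    """
    sub = m.loc[members]
    if sub.shape[0] < 4:
        raise ValueError(f"environment {environment_id!r} has fewer than 4 species")
    by_dir = _pairs_by_direction(assoc, m.columns, use_all_pairs)
    pairs = sorted(set(by_dir[POSITIVE]) | set(by_dir[NEGATIVE]))
    if not pairs:
        raise ValueError("no evaluable trait pairs")
    x = sub.to_numpy(dtype=np.int8)
    if n_swaps is None:
        n_swaps = max(100, recommended_swaps(x))
    ens = build_ensemble(x, pairs, n_perm=n_perm, n_swaps=n_swaps, seed=seed)
    where = {p: k for k, p in enumerate(pairs)}
    results = []
    for direction in (POSITIVE, NEGATIVE):
        idx = [where[p] for p in by_dir[direction]]
        if not idx:
            continue
        if direction == POSITIVE:
            dev = ens.pos_obs[idx] - ens.mean_pos[idx]
        else:
            dev = ens.neg_obs[idx] - ens.mean_neg[idx]
        results.append(DeviationResult(
            environment_id=environment_id,
            direction=direction,
            n_species=sub.shape[0],
            n_pairs=len(idx),
            mean_deviation=float(dev.mean()),
            sd_deviation=float(dev.std(ddof=1)) if len(idx) > 1 else 0.0,
        ))
    return results


def all_environment_deviations(
    m: pd.DataFrame,
    env: pd.DataFrame,
    assoc: pd.DataFrame,
    n_perm: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
    min_species: int = 4,
) -> pd.DataFrame:
    """Deviation summary for every eligible environment."""
    rows = []
    rng = np.random.default_rng(seed)
    for e in env.columns:
        mask = env[e].astype(bool)
        if mask.sum() < min_species:
            log.info("environment %r ineligible (%d species)", e, int(mask.sum()))
            continue
        for res in environment_deviation(
            m, mask, assoc, environment_id=str(e), n_perm=n_perm,
            n_swaps=n_swaps, seed=int(rng.integers(2**31 - 1)),
        ):
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def random_sampling_control(
    m: pd.DataFrame,
    assoc: pd.DataFrame,
    sizes=CONTROL_SIZES,
    reps: int = 1000,
    n_perm: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Environment-free control: random species draws of each sample size.

    For each size, ``reps`` random subsets are pushed through the same
    deviation computation (as synthetic environments named ``random:n``) and
    the per-direction deviations are averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        if n > m.shape[0]:
            raise ValueError(f"sample size {n} exceeds species count {m.shape[0]}")
        acc: dict[str, list[float]] = {POSITIVE: [], NEGATIVE: []}
        for _ in range(reps):
            members = rng.choice(m.index.to_numpy(), size=n, replace=False)
            for res in environment_deviation(
                m, members, assoc, environment_id=f"random:{n}",
                n_perm=n_perm, n_swaps=n_swaps, seed=int(rng.integers(2**31 - 1)),
            ):
                acc[res.direction].append(res.mean_deviation)
        for direction, vals in acc.items():
            if not vals:
                continue
            v = np.asarray(vals)
            rows.append({
                "environment_id": f"random:{n}",
                "direction": direction,
                "n_species": n,
                "n_pairs": len(v),
                "mean_deviation": float(v.mean()),
                "sd_deviation": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
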