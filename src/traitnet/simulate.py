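"""Synthetic inputs with the statistical structure the pipeline assumes.

The trait generator draws species trait vectors from a pairwise log-linear
(Ising-like) model: each trait has a baseline prevalence, traits inside a
planted module attract each other (positive log-odds interaction), and
planted exclusion pairs repel.  Sampling is by Gibbs sweeps with a fixed
burn-in; baseline logits carry a mean-field correction so realized
prevalences stay near their targets despite the interactions.  Around the
trait matrix the module fabricates the companion inputs: a missing-data mask,
a Yule tree with threshold-Brownian (or tip-shuffled) trait histories,
isolation environments enriched for trait suites, and gene columns causally
tied to traits.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .data_io import ABSENT, MISSING, PRESENT, VARIABLE
from .phylo_signal import TreeIndex, brownian_threshold_states

#: environment sizes always present among the generated environments
ENV_SIZE_GRID = (4, 11, 26, 47, 76, 147, 217)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset (for recovery scoring)."""

    modules: list[list[int]]            # trait-index sets with positive interactions
    negative_pairs: list[tuple[int, int]]
    module_boost: float                 # log-odds interaction inside modules
    negative_strength: float            # log-odds for exclusion pairs (negative)
    prevalence: np.ndarray              # per-trait target prevalence
    missing_rate: float
    variable_rate: float
    env_suites: dict[str, list[int]] = field(default_factory=dict)
    env_sizes: dict[str, int] = field(default_factory=dict)
    gene_map: dict[str, int] = field(default_factory=dict)
    gene_noise: float = 0.1
    seed: int = 0

    def interaction_matrix(self, n_traits: int) -> np.ndarray:
        J = np.zeros((n_traits, n_traits))
        for mod in self.modules:
            for i in mod:
                for j in mod:
                    if i != j:
                        J[i, j] = self.module_boost
        for i, j in self.negative_pairs:
            J[i, j] = J[j, i] = self.negative_strength
        return J

    def module_pairs(self) -> list[tuple[int, int]]:
        out = []
        for mod in self.modules:
            out += [(a, b) for k, a in enumerate(mod) for b in mod[k + 1:]]
        return out


def default_truth(
    n_traits: int = 48,
    seed: int = 0,
    n_modules: int = 4,
    module_size: int = 4,
    module_boost: float = 2.0,
    n_negative_pairs: int = 4,
    negative_strength: float = -2.0,
    missing_rate: float = 0.06,
    variable_rate: float = 0.06,
) -> SyntheticTruth:
    """Planted structure mirroring the study conditions.

    Defaults: e^2 odds boost inside four 4-trait modules, four exclusion
    pairs, ~6% missing cells, ~6% of positive cells scored "variable".
    """
    rng = np.random.default_rng(seed)
    traits = rng.permutation(n_traits)
    need = n_modules * module_size + 2 * n_negative_pairs
    if need > n_traits:
        raise ValueError("too few traits for the requested planted structure")
    modules = [sorted(traits[k * module_size:(k + 1) * module_size].tolist())
               for k in range(n_modules)]
    rest = traits[n_modules * module_size:]
    negative_pairs = [(int(rest[2 * k]), int(rest[2 * k + 1]))
                      for k in range(n_negative_pairs)]
    prevalence = rng.uniform(0.2, 0.8, size=n_traits)
    return SyntheticTruth(
        modules=modules, negative_pairs=negative_pairs,
        module_boost=module_boost, negative_strength=negative_strength,
        prevalence=prevalence, missing_rate=missing_rate,
        variable_rate=variable_rate, seed=seed,
    )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def simulate_binary_traits(
    n_species: int,
    truth: SyntheticTruth,
    seed: int = 0,
    burn_in: int = 100,
    calibration_sweeps: int = 60,
) -> np.ndarray:
    """Gibbs-sample species x trait binary states from the log-linear model.

    Baseline logits start at a mean-field correction and are refined by
    stochastic approximation during ``calibration_sweeps`` extra sweeps
    (matching realized to target prevalences, which plain mean-field misses
    under strong coupling), then frozen for the final ``burn_in`` sweeps.
    """
    n_traits = len(truth.prevalence)
    p = np.asarray(truth.prevalence, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("target prevalences must lie strictly in (0, 1)")
    J = truth.interaction_matrix(n_traits)
    if np.abs(J).max() > 10:
        raise ValueError("interaction magnitude too large for stable sampling")
    target_logit = np.log(p / (1 - p))
    base = target_logit - J @ p
    rng = np.random.default_rng(seed)
    x = (rng.random((n_species, n_traits)) < p).astype(np.int8)

    def sweep():
        for t in range(n_traits):
            logit = base[t] + x @ J[:, t]
            x[:, t] = rng.random(n_species) < _sigmoid(logit)

    for s in range(calibration_sweeps):
        sweep()
        realized = np.clip(x.mean(axis=0), 1 / (2 * n_species), 1 - 1 / (2 * n_species))
        eta = 2.0 / (1 + s / 10)
        base += eta * (target_logit - np.log(realized / (1 - realized)))
    for _ in range(burn_in):
        sweep()
    return x


def simulate_trait_matrix(
    n_species: int = 784,
    n_traits: int = 48,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, SyntheticTruth]:
    """Coded (+/-/v/n-style) trait table plus the underlying complete matrix.

    Returns ``(coded, complete, truth)``: the coded frame uses the canonical
    code strings with MCAR missingness at ``truth.missing_rate`` and a
    fraction of positive cells marked variable; ``complete`` is the unmasked
    binary matrix for recovery scoring.
    """
    if truth is None:
        truth = default_truth(n_traits, seed=seed)
    if len(truth.prevalence) != n_traits:
        raise ValueError("truth prevalence length must equal n_traits")
    rng = np.random.default_rng(seed)
    x = simulate_binary_traits(n_species, truth, seed=int(rng.integers(2**31 - 1)))
    species = [f"sp{i:04d}" for i in range(n_species)]
    traits = [f"trait{j:02d}" for j in range(n_traits)]
    codes = np.where(x == 1, PRESENT, ABSENT).astype(object)
    variable = (x == 1) & (rng.random(x.shape) < truth.variable_rate)
    codes[variable] = VARIABLE
    mask = rng.random(x.shape) < truth.missing_rate
    codes[mask] = MISSING
    coded = pd.DataFrame(codes, index=species, columns=traits)
    return coded, x, truth


def simulate_tree_and_traits(
    n_tips: int,
    prevalences,
    modes,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Yule tree (depth scaled to 1) with per-trait evolved tip states.

    ``modes`` holds one of ``{"brownian", "shuffled"}`` per trait: brownian
    states come from thresholded Brownian motion at the trait's prevalence
    (phylogenetic signal present); shuffled states are the same values
    randomly reassigned to tips (signal destroyed, identical prevalence).
    """
    if n_tips < 8:
        raise ValueError("need at least 8 tips")
    if len(prevalences) != len(modes):
        raise ValueError("prevalences and modes must align")
    rng = np.random.default_rng(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(int(rng.integers(2**31 - 1))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:04d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    idx = TreeIndex.from_tree(tree)
    cols = {}
    for t, (p, mode) in enumerate(zip(prevalences, modes)):
        k = int(round(p * n_tips))
        k = min(max(k, 1), n_tips - 1)
        states = brownian_threshold_states(idx, k, rng, n_rep=1)[:, 0]
        if mode == "shuffled":
            states = rng.permutation(states)
        elif mode != "brownian":
            raise ValueError(f"unknown mode {mode!r}")
        cols[f"trait{t:02d}"] = states.astype(int)
    tips = pd.DataFrame(cols, index=idx.tip_labels)
    return tree.as_string(schema="newick"), tips


def simulate_environment_driven(
    n_species: int,
    n_traits: int,
    suites: list[list[int]],
    base_prevalence: float = 0.3,
    suite_prevalence: float = 0.85,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Traits driven purely by a latent environment (no intrinsic interactions).

    Each species belongs to exactly one environment; environment ``e`` raises
    the prevalence of its suite traits from ``base_prevalence`` to
    ``suite_prevalence``; conditional on the environment all traits are
    independent.  Marginally the suite traits co-occur, but within any one
    environment the fixed-margin null reproduces the pair counts — the
    regime in which trait associations are attributable to environment.
    Returns ``(binary trait frame, binary environment frame)``.
    """
    rng = np.random.default_rng(seed)
    n_env = len(suites)
    if n_env < 2:
        raise ValueError("need at least 2 environments")
    member = rng.integers(0, n_env, size=n_species)
    p = np.full((n_species, n_traits), base_prevalence)
    for e, suite in enumerate(suites):
        p[np.ix_(member == e, suite)] = suite_prevalence
    x = (rng.random((n_species, n_traits)) < p).astype(np.int8)
    species = [f"sp{i:04d}" for i in range(n_species)]
    traits = pd.DataFrame(x, index=species,
                          columns=[f"trait{j:02d}" for j in range(n_traits)])
    env = pd.DataFrame(
        {f"env{e:02d}": (member == e).astype(int) for e in range(n_env)},
        index=species)
    return traits, env


def simulate_environments_and_genes(
    x: np.ndarray,
    truth: SyntheticTruth,
    seed: int = 0,
    n_environments: int = 50,
    suite_size: int = 3,
    enrichment: float = 6.0,
    module_suite_fraction: float = 0.5,
    n_gene_species: int = 79,
    genes_per_trait: int = 1,
):
    """Environment and gene tables causally linked to the trait matrix.

    Each environment has a random trait suite; its members are drawn without
    replacement with weights exp(enrichment * suite score), so member species
    are enriched for the suite.  Environment sizes always include the
    control grid {4, 11, 26, 47, 76, 147, 217}.  A fraction
    ``module_suite_fraction`` of environments take a planted module as their
    suite (environment-linked trait syndromes); the rest use random traits.
    Each mapped gene is present with probability 1 - noise when its trait is
    present and noise otherwise.
    Returns ``(env_frame, gene_frame)`` and records suites/sizes/gene map on
    ``truth``.
    """
    rng = np.random.default_rng(seed)
    n_species, n_traits = x.shape
    species = [f"sp{i:04d}" for i in range(n_species)]
    sizes = [s for s in ENV_SIZE_GRID if s <= n_species]
    while len(sizes) < n_environments:
        sizes.append(int(rng.integers(4, min(220, n_species) + 1)))
    sizes = sizes[:n_environments]
    env_cols = {}
    for e, size in enumerate(sizes):
        if truth.modules and rng.random() < module_suite_fraction:
            suite = list(truth.modules[int(rng.integers(len(truth.modules)))])
        else:
            suite = rng.choice(n_traits, size=suite_size, replace=False).tolist()
        score = x[:, suite].mean(axis=1)
        w = np.exp(enrichment * score)
        members = rng.choice(n_species, size=size, replace=False, p=w / w.sum())
        col = np.zeros(n_species, dtype=int)
        col[members] = 1
        name = f"env{e:02d}"
        env_cols[name] = col
        truth.env_suites[name] = [int(s) for s in suite]
        truth.env_sizes[name] = size
    env = pd.DataFrame(env_cols, index=species)

    sub = rng.choice(n_species, size=min(n_gene_species, n_species), replace=False)
    sub.sort()
    gene_cols = {}
    for t in range(n_traits):
        for g in range(genes_per_trait):
            name = f"gene_t{t:02d}_{g}"
            flip = rng.random(len(sub)) < truth.gene_noise
            gene_cols[name] = np.where(flip, 1 - x[sub, t], x[sub, t])
            truth.gene_map[name] = t
    genes = pd.DataFrame(gene_cols, index=[species[i] for i in sub])
    return env, genes
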