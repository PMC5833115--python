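# traitnet

Pairwise association analysis of binary phenotypic traits across species,
with attribution of the detected structure to phylogeny, intrinsic biological
properties, and isolation environments.

The package grew out of comparative microbiology: budding-yeast taxonomy
provides hundreds of species scored for growth (+), no growth (−), variable
(v) or unknown (n) on dozens of conditions — carbon and nitrogen sources,
fermentation of sugars, growth at elevated temperature.  Such traits do not
evolve independently: some co-occur far more often than chance (shared
pathways, promiscuous enzymes), others exclude each other (trade-offs,
host-associated lifestyles).  `traitnet` is for researchers who want to
quantify those associations rigorously and ask *why* they exist.

## The statistics at its core

**Association calls.**  For a binary species × trait matrix and a trait pair
(a, b), the positive count is `obs(1,1)` and the negative count
`obs(1,0) + obs(0,1)`.  Expected counts are means over fixed-margin
permutations of the matrix produced by checkerboard swaps (random 2×2
submatrices `[[1,0],[0,1]] ↔ [[0,1],[1,0]]`, preserving all row and column
sums).  The strength of an association is

```
Str_pos = |Positive_obs − mean(Pos_exp)|,   Str_neg = |Negative_obs − mean(Neg_exp)|
```

with one-sided empirical permutation p-values (add-one corrected),
Benjamini–Hochberg adjusted within each direction; q < 0.05 is called
significant.  The same machinery tests trait–environment associations with
the environment columns held fixed.

**Missing data.**  A missing cell is imputed from the zero-probability rule
`P(0) = T(z) · P(s) · P(t)` — the whole-matrix zero proportion times the
species' and the trait's observed zero fractions; `P(0) > 0.5` fills 0,
otherwise 1.

**Phylogenetic signal.**  Per trait, the D statistic of binary-trait
dispersion: the sum of sister-clade differences of tip states averaged up the
tree, scaled between a tip-shuffle null (D = 1) and a threshold-Brownian null
(D = 0).

**Attribution.**  Variance partitioning of the species × trait-pair
co-occurrence indicator over three predictor blocks — principal coordinates
of the tree's patristic distances, per-category utilization counts, and the
binary environment matrix — via inclusion–exclusion of Ezekiel-adjusted
redundancy R²; deviations of observed vs expected pair counts *within* each
environment against random species draws; greedy-modularity (CNM)
communities of the signed association networks with Fisher-exact category
enrichment; and gene-level corroboration (χ² of gene presence × growth,
equal-proportions test of gene co-occurrence within vs between trait
communities).

## Worked example

`analysis/` holds the numbered pipeline over a fully synthetic study dataset
(784 species × 48 traits with four planted 4-trait modules at an e² odds
boost, four exclusion pairs, ~6% missing cells, 50 environments, a 200-tip
Yule tree, and a 79-species gene table).  Running the scripts in order:

```
$ python analysis/01_simulate_dataset.py
trait table: 784 species x 48 traits, 6.1% missing
planted modules: [[10, 20, 22, 42], [18, 31, 33, 46], [28, 30, 37, 41], [6, 8, 25, 36]]; ...

$ python analysis/02_impute_and_associate.py
imputed 2311 missing cells (100% to presence)
trait pairs: 1128 tested, 28 significant (24 positive, 4 negative) at q<0.05

$ python analysis/04_phylogenetic_signal.py
brownian: mean D = -0.013 over 24 traits
shuffled: mean D = 0.992 over 24 traits

$ python analysis/06_environment_deviation.py
intrinsic regime (study dataset): associations persist inside environments
  positive: median |deviation| 15.16 within environments, 4.67 in random draws
environment-driven regime: environments absorb the associations
  positive: median |deviation| 0.43 within environments, 12.09 in random draws

$ python analysis/07_networks_and_genes.py
positive: 16 nodes, 24 edges, 4 communities (Q=0.748); top enrichment: community 0 x module3 (p=5.49e-04)
sign enrichment among module-trait pairs: table [[24, 0], [0, 4]], p=4.88e-05
gene co-occurrence within communities 29.5% vs between 24.1% (chi2=8.11, p=0.00441)
```

The 24 positive calls are exactly the planted module pairs and the 4 negative
calls the planted exclusion pairs; traits evolved under thresholded Brownian
motion average D ≈ 0 while tip-shuffled traits average D ≈ 1; and the
environment-deviation contrast separates intrinsically driven from
environment-driven association structure.  A `traitnet` console script
exposes the same steps as subcommands (`simulate`, `impute`, `associate`,
`cluster`, `signal`, `varpart`, `envdev`, `network`, `genes`) for use on your
own TSV/newick inputs.

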