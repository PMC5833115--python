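# Methods

This note documents the models implemented in `traitnet`, the defaults and
their rationale, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Trait coding and filtering

Trait tables arrive coded `+` (growth), `−` (no growth), `v` (variable among
assayed strains), `n` (no data); synonyms `1/0/V/NA` are accepted.  Variable
scores are treated as presence — a variable score means at least one strain
grew.  Coverage filtering removes traits observed in fewer than 80% of
species, then species with data for fewer than 20% of the remaining traits
(`trait_min=0.8`, `species_min=0.2`, both configurable).  Traits are filtered
first because the trait rule is the stronger one and species coverage is only
meaningful over the retained traits; the filter is idempotent and never
alters a retained cell.

## Imputation

For a missing cell, `P(0) = T(z) · P(s) · P(t)` with `P(s) = n0/n_s` and
`P(t) = n0/n_t` the observed zero fractions of the cell's species row and
trait column, and `T(z) = n0_total/(n_r · n_c)` the whole-matrix zero
proportion — the denominator deliberately counts all cells, observed or not,
following the rule as defined.  `P(0) > 0.5` fills 0, below fills 1; an exact
tie fills 1 (the "below 0.5" branch taken as the closed half) and is logged.
All statistics are frozen from the pre-imputation matrix, so the result is
independent of fill order and fully deterministic.

Because `P(0)` is a product of three fractions it exceeds 0.5 only on very
zero-heavy rows/columns; on matrices dominated by presences nearly all
missing cells impute to 1.  This is a property of the rule, implemented
verbatim, not a defect of the implementation; the test suite shows the rule
beats both constant fills on matrices with strongly heterogeneous trait
prevalences, which is the regime it is designed for.

## The fixed-margin null

A permutation is the state of the checkerboard-swap chain after `n_swaps`
*attempted* swaps from the observed matrix; a draw that hits no checkerboard
leaves the matrix in place.  This choice matters: the hold-in-place chain is
symmetric, so its stationary distribution is uniform over the fixed-margin
class, which we verify against exhaustive enumeration of a 3×3 margin class
(pair-count means agree within 1%, visitation frequencies uniform).  Counting
only *successful* swaps and stopping after a fixed number of them weights
states by their checkerboard count — on the enumerable class that biases
pair-count means by 5–23% — so successful-swap counting is available as an
option (`count_successful=True`) but is not the default.

Chain mixing scales with the number of 1s in the matrix.  On the 784×48
study-shaped matrix (~28k ones) the conventional 1000 swaps per permutation
is far from mixed; `recommended_swaps` (5 × the 1-count) is used by the
calibration suite and the deviation analyses, while `n_swaps=1000` remains
the protocol default for comparability.  Each replicate restarts from the
observed matrix (no chaining), and ensembles store only streaming summaries
(null means and exceedance tallies per pair), so memory is O(pairs).

## Association calls

Empirical one-sided p-values use the add-one correction
`p = (1 + #{null ≥ obs}) / (n_perm + 1)`; a Wilson interval on the exceedance
proportion is carried as a stability diagnostic.  BH runs separately within
the positive-test and negative-test families (a pooled-family switch exists);
direction is `none` iff both sides have q ≥ α, and for such pairs the side
with the larger |obs − exp| is additionally reported.  Note the p-floor
interacts with BH: at 1,000 permutations the smallest attainable q over ~200
pairs is ≈ 0.1 unless several pairs sit at the floor, so genuine effects need
the full 10,000 permutations to clear q < 0.05 in realistic batch sizes.
Trait–environment tests permute only the trait matrix; environment columns
are fixed covariates, and environments with fewer than 4 member species are
ineligible.

## Trait clustering

A trait's profile is its row of the signed strength matrix (+Str for
significant positive partners, −Str for negative, 0 otherwise).  Signed
encoding preserves the positive/negative distinction that an absolute-value
encoding would collapse.  Distances are Euclidean over the full aligned rows;
clustering is Ward on those distances (scipy's `ward` on a condensed
distance matrix, i.e. the squared-update Ward.D2 convention; the method
string is configurable).  Support is the plain bootstrap probability of each
node's tip set under resampling of profile coordinates; with only T−1
informative coordinates per trait, support values are conservative for small
modules — block structure needs several members before nodes reach 0.95.

## Phylogenetic signal

Nodal values are tips-to-root unweighted means of daughter values (topology
only); d is the sum over internal nodes of |daughter difference|, a polytomy
contributing the mean over its daughter pairs (keeps its scale comparable to
a bifurcation), and a unifurcation contributing nothing.  Branch lengths
enter only the Brownian null: increments Normal(0, branch length) from the
root, thresholded at rank so that exactly the observed number of tips score 1.
D = (d_obs − mean d_Brownian)/(mean d_random − mean d_Brownian) with 1000
simulations per null by default; two-sided p-values are 2·min(tail, 1−tail),
capped at 1, each tail add-one corrected.  Species absent from the tree are
dropped per analysis with a logged count; traits constant on the shared tips
are skipped.  Calibration: threshold-Brownian traits average D ≈ 0 and
tip-shuffled traits D ≈ 1 (both within ±0.15 at 200 traits on a 200-tip
Yule tree).

## Variance partitioning

The response codes a species–pair cell 1 iff both traits are present; the
both-absent case is 0 (the only consistent binary completion).  Explained
variance is linear redundancy R² (no logistic link, matching standard
variance-partitioning machinery), Ezekiel-adjusted with p = effective rank of
the predictor block.  Fractions come from inclusion–exclusion over the seven
predictor-set unions; they reproduce the total to numerical precision, and
individual fractions may be slightly negative — an artifact of the
adjustment that is reported as computed.  With a *noise-free* response the
adjustment pushes chance-level R² of inactive blocks deterministically
negative (−p/(n−p−1)); the calibration checks therefore use a noisy
response, the regime the adjustment assumes.  Phylogeny is represented by
principal coordinates of the patristic distance matrix, keeping
positive-eigenvalue axes to 95% cumulative eigenvalue mass — raw n×n
distance columns would make adjusted R² degenerate; the retention fraction
is exposed because reported fractions are mildly sensitive to it.

## Environment deviations

For one environment, the deviation of a trait pair is its observed count in
the member submatrix minus the mean of a fresh swap ensemble built *on that
submatrix* (restricting global permutations would not preserve subset
margins).  Evaluated pairs default to those significant in the global
analysis; means and SDs are reported separately for positive- and
negative-direction pairs.  The random-draw control pushes subsets of sizes
{4, 11, 26, 47, 76, 147, 217} through the identical code path.  An
"environment" holding every species simply re-measures the global analysis —
its mean deviation equals the mean global strength, not zero, whenever
associations exist.  Deviations near zero within real environments, combined
with large deviations in the random control, indicate environment-driven
association structure; the two synthetic regimes in
`analysis/06_environment_deviation.py` demonstrate both signatures.

## Networks, communities, enrichment

Networks take one node per trait with at least one significant association
of the given sign and one edge per significant same-sign pair, weighted by
strength.  Communities come from greedy modularity agglomeration (CNM) on the
weighted graph (unweighted mode available), with deterministic ordering of
the returned partition.  Greedy agglomeration attains the exact
maximum-modularity partition on modular, clique-like graphs — verified
against brute force on every test graph up to 8 nodes — but is a heuristic
and is known to fall short on chain- and ring-like graphs; association
networks are of the former kind.  Enrichment per (community, category) uses
two-sided Fisher exact tests over the network's nodes, and the
positive-vs-negative sign enrichment uses the 2×2 table
{carbon–carbon pairs, other significant pairs} × {positive, negative} (a
binomial 50/50 alternative is available behind a flag, since the exact table
construction is a genuine design freedom).

## Gene–trait statistics

Gene-growth association is χ² on the full 2×2 presence × growth table
without continuity correction; the reported "same" (present ∧ growth) and
"different" (absent ∧ growth + present ∧ ¬growth) counts are summaries of
that table, not the test's entire input — a 2-cell χ² would need an
arbitrary expected split.  Constant columns make the test undefined and are
skipped with a note; BH runs across the scan.  Gene co-occurrence pools
events over species × pairs (per-pair averaging available as a diagnostic)
and compares within-group vs between-group proportions with a Yates-corrected
equal-proportions χ², the convention of standard two-proportion tests.
Closely related paralogs can be collapsed into an any-of presence column
first.

## Synthetic data

The generator draws species trait vectors from a pairwise log-linear (Ising)
model: per-trait baseline prevalences (default U(0.2, 0.8)), +2 log-odds
interactions inside each planted module (an e² odds boost), −2 for exclusion
pairs.  Gibbs sampling runs 60 calibration sweeps — a stochastic
approximation adjusts baseline logits so realized prevalences match their
targets, which a one-shot mean-field correction misses under strong coupling
— followed by 100 frozen burn-in sweeps.  Defaults mirror the study shape:
784 species, 48 traits, four 4-trait modules, four exclusion pairs, 6%
missing completely at random, ~6% of positive cells marked variable, 50
environments whose sizes always include the control grid, half of them
enriched (weight ∝ exp(6 · suite score)) for a planted module's trait suite,
and one gene per trait present with probability 0.9 given its trait.  Trees
are Yule (pure birth) scaled to unit depth, with per-trait threshold-Brownian
or tip-shuffled histories.

A second generator (`simulate_environment_driven`) produces traits that are
conditionally independent given a single latent environment, the regime in
which associations are entirely attributable to environment.  What the
generators do *not* emulate: phylogenetically autocorrelated trait matrices
(tree traits and matrix traits are generated separately), hierarchical
broad/specific environment nesting, margins matching any real dataset, or
correlated missingness.  Passing tests therefore demonstrate calibration and
recovery under the stated models, not performance on real data with
confounded phylogeny and ecology.

## Problem sizes in the test and calibration suites

Chosen so the full suite runs in minutes on one core: enumeration checks on
the 5-member 3×3 margin class (10,000-permutation ensembles, averaged over
25 ensembles for the 1% bias check — a single ensemble's Monte-Carlo s.e. on
the smallest pair mean is ~2%); type-I on 20 datasets of 500×20 at 1,000
permutations; power on 10 planted datasets at 4,000 permutations with
mixing-scaled swaps; D calibration on 200+200 traits with 200 simulations
per null; variance-partition checks at n = 1000; community detection against
brute force on ≤8-node graphs; Fisher vs hypergeometric enumeration on all
2×2 tables with n ≤ 12.
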