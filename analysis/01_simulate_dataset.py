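"""Generate the synthetic study dataset.

Emulates the shape of the yeast trait survey: 784 species x 48 binary growth
traits with planted positive modules and exclusion pairs, ~6% missing cells,
50 isolation environments (sizes covering the 4-217 control grid, half of
them enriched for a planted module's trait suite), a 200-tip Yule phylogeny
with threshold-Brownian trait histories, and a 79-species gene-presence table
causally tied to traits.  Writes everything under results/synthetic/.
"""

import json
from pathlib import Path

from traitnet import data_io, simulate

OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260921

coded, complete, truth = simulate.simulate_trait_matrix(784, 48, seed=SEED)
data_io.write_trait_table(coded, OUT / "traits_coded.tsv")

env, genes = simulate.simulate_environments_and_genes(complete, truth, seed=SEED + 1)
data_io.write_binary_table(env, OUT / "environments.tsv")
data_io.write_binary_table(genes, OUT / "genes.tsv")

prevalence = complete.mean(axis=0)
modes = ["brownian" if j % 2 == 0 else "shuffled" for j in range(48)]
newick, tips = simulate.simulate_tree_and_traits(200, prevalence, modes, seed=SEED + 2)
(OUT / "tree.nwk").write_text(newick)
data_io.write_binary_table(tips, OUT / "tree_tip_traits.tsv")

# functional categories for the biology predictors and network enrichment:
# module traits share their module's category; the rest are binned round-robin
category = {}
for k, module in enumerate(truth.modules):
    for j in module:
        category[f"trait{j:02d}"] = f"module{k}"
rest = [j for j in range(48) if f"trait{j:02d}" not in category]
for i, j in enumerate(rest):
    category[f"trait{j:02d}"] = f"background{i % 4}"
with open(OUT / "trait_categories.tsv", "w") as fh:
    fh.write("trait\tcategory\n")
    for t in sorted(category):
        fh.write(f"{t}\t{category[t]}\n")

record = {
    "seed": SEED,
    "modules": truth.modules,
    "negative_pairs": [list(p) for p in truth.negative_pairs],
    "module_boost": truth.module_boost,
    "negative_strength": truth.negative_strength,
    "missing_rate": truth.missing_rate,
    "env_suites": truth.env_suites,
    "env_sizes": truth.env_sizes,
    "gene_map": truth.gene_map,
    "tree_trait_modes": modes,
}
(OUT / "truth.json").write_text(json.dumps(record, indent=2))

n_missing = (coded == data_io.MISSING).to_numpy().sum()
print(f"trait table: {coded.shape[0]} species x {coded.shape[1]} traits, "
      f"{100 * n_missing / coded.size:.1f}% missing")
print(f"planted modules: {truth.modules}; exclusion pairs: {truth.negative_pairs}")
print(f"environments: {env.shape[1]} (sizes {sorted(set(truth.env_sizes.values()))[:8]}...)")
print(f"gene table: {genes.shape[0]} species x {genes.shape[1]} genes")
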