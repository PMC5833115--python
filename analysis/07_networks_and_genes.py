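"""Association networks, their communities, and the gene-level corroboration.

Builds the positive and negative association networks over all traits (in
this synthetic study every trait plays the role of a carbon source), detects
greedy-modularity communities, tests category enrichment per community and
the positive-vs-negative sign enrichment, then associates gene presence with
growth and compares gene co-occurrence within vs between the two largest
communities' gene sets.
"""

import json
from pathlib import Path

import pandas as pd

from traitnet import data_io, genes, networks

OUT = Path("results")
SYN = OUT / "synthetic"

assoc = pd.read_csv(OUT / "trait_associations.tsv", sep="\t")
cat = pd.read_csv(SYN / "trait_categories.tsv", sep="\t", index_col=0)["category"].to_dict()
traits = sorted(cat)

for sign in ("positive", "negative"):
    g = networks.build_network(assoc, sign, traits, category_map=cat)
    if g.number_of_edges() == 0:
        print(f"{sign}: no significant edges")
        continue
    comms, q = networks.cnm_communities(g)
    networks.export_edge_list(g, comms, OUT / f"{sign}_network_edges.tsv")
    enrich = networks.community_enrichment(g, comms, cat)
    enrich.to_csv(OUT / f"{sign}_community_enrichment.tsv", sep="\t", index=False)
    best = enrich.nsmallest(1, "p").iloc[0]
    print(f"{sign}: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges, "
          f"{len(comms)} communities (Q={q:.3f}); top enrichment: community "
          f"{best.community} x {best.category} (p={best.p:.2e})")

# the module-category traits play the carbon-utilization role: are pairs among
# them biased toward positive (vs negative) calls relative to all other pairs?
carbon_like = [t for t, c in cat.items() if c.startswith("module")]
res = networks.sign_enrichment(assoc, carbon_like)
print(f"sign enrichment among module-trait pairs: table {res['table']}, p={res['p']:.3g}")

gene_table = data_io.read_gene_table(SYN / "genes.tsv")
growth = pd.read_csv(OUT / "traits_imputed.tsv", sep="\t", index_col=0).loc[gene_table.index]
combined = pd.concat([gene_table, growth], axis=1)
truth_map = json.loads((SYN / "truth.json").read_text())["gene_map"]

gene_cols = list(gene_table.columns)[:12]
carbon_cols = [f"trait{truth_map[g]:02d}" for g in gene_cols]
scan = genes.gene_growth_scan(combined, gene_cols, sorted(set(carbon_cols)))
scan.to_csv(OUT / "gene_growth_chi2.tsv", sep="\t", index=False)
matched = scan[[t == f"trait{truth_map[g]:02d}"
                for g, t in zip(scan.gene, scan.carbon)]]
print(f"gene-growth scan: {len(scan)} tests, {(scan.q < 0.05).sum()} significant; "
      f"{(matched.q < 0.05).sum()}/{len(matched)} causal gene-trait pairs recovered")

# genes of two positively associated trait communities: within-community gene
# pairs should co-occur more often than cross-community pairs
truth = json.loads((SYN / "truth.json").read_text())
by_trait = {t: g for g, t in truth_map.items()}
g1 = [by_trait[j] for j in truth["modules"][0]]
g2 = [by_trait[j] for j in truth["modules"][1]]
co = genes.co_occurrence_test(combined, g1, g2)
print(f"gene co-occurrence within communities {co.within_freq:.1%} vs between "
      f"{co.between_freq:.1%} (chi2={co.chi2:.2f}, p={co.p:.3g})")
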