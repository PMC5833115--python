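"""Cluster traits by the similarity of their association profiles.

Builds the signed strength matrix (positive partners +, negative partners -,
non-significant 0), computes Euclidean distances, applies Ward clustering,
and attaches coordinate-bootstrap support; writes the dendrogram as newick
with supports as node labels.
"""

import json
from pathlib import Path

import pandas as pd

from traitnet import clustering

OUT = Path("results")
SEED = 20260921

table = pd.read_csv(OUT / "trait_associations.tsv", sep="\t")
prof = clustering.association_profiles(table)
dist = clustering.profile_distance(prof)
Z = clustering.ward_cluster(dist)
support = clustering.cluster_support(prof, n_boot=500, seed=SEED)
(OUT / "trait_dendrogram.nwk").write_text(
    clustering.linkage_to_newick(Z, list(prof.index), support))

truth = json.loads((OUT / "synthetic" / "truth.json").read_text())
supported = support[support >= 0.95]
print(f"{len(prof)} traits clustered; {len(supported)} node(s) with support >= 0.95")
for module in truth["modules"]:
    names = frozenset(f"trait{j:02d}" for j in module)
    bp = support.get(names)
    bp = float(bp) if bp is not None else float("nan")
    print(f"planted module {sorted(module)}: bootstrap support {bp:.2f}")
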