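"""Trunk/branch/private structure, a parsimony tree and clonal architecture
for one simulated tumor."""

import numpy as np
import pandas as pd

from ithseq.genomic_ith import (
    build_parsimony_tree, classify_trunk_branch_private,
    cluster_clonal_architecture, estimate_ccf, merge_regions, mutation_matrix,
    mutational_jaccard,
)
from ithseq.synthetic_cohort import SimulationConfig, simulate_cohort
from ithseq.variant_filtering import filter_and_rescue

cohort, truth = simulate_cohort(SimulationConfig(n_patients=1, seed=2))
b = cohort.bundles["P01"]
kept = filter_and_rescue(b.variants)

mat = mutation_matrix(kept, b.regions)
labels = classify_trunk_branch_private(mat)
counts = labels["label"].value_counts()
print("mutation classes:", {k: int(v) for k, v in counts.items()})
print(f"trunk fraction {counts.get('trunk', 0) / len(labels):.3f} "
      f"(ground truth {truth.trunk_fraction('P01'):.3f})")

pairs, mean_ji = mutational_jaccard(mat)
print(f"mean pairwise mutational Jaccard index: {mean_ji:.3f}")

tree = build_parsimony_tree(mat)
print(f"parsimony tree, {tree.total_length} changes "
      f"({tree.trunk_count} on the trunk): {tree.newick()}")

merged = merge_regions(kept)
purity = float(np.mean(list(b.purity.values())))
raw_ccf = pd.Series([estimate_ccf(v, purity)[1] for v in merged["t_vaf"]])
arch = cluster_clonal_architecture(raw_ccf)
print(f"CCF clustering chose k={arch.k}; clonal fraction "
      f"{arch.clonal_fraction:.2f} (mutations in the highest-prevalence cluster)")
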