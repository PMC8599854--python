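"""Gene-level copy-number calls, burden, between-region overlap and LOH."""

from ithseq.cna_analysis import (
    classify_gene_loh, cna_burden, cna_jaccard, default_gene_model,
    gene_level_cna, trunk_branch_loh,
)
from ithseq.synthetic_cohort import SimulationConfig, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(n_patients=4, seed=9))
genes = default_gene_model()

calls = gene_level_cna(cohort.segments, genes)
burden = cna_burden(calls)
pairs, means = cna_jaccard(calls)
loh = classify_gene_loh(cohort.segments, genes)
events, frac = trunk_branch_loh(loh)

region = burden[burden["region_id"] != "tumor"]
print(f"{len(calls)} gene-level calls across "
      f"{region.shape[0]} regions")
print(f"median per-region CNA burden: {region['cna_burden'].median():.0f} genes "
      "(gain or loss, strict +/-0.6 log2 thresholds)")
print(f"median CNA Jaccard index between regions: {means['jaccard'].median():.2f}")
n_loh = (loh["loh_class"] != "none").sum()
print(f"{n_loh} gene-region LOH calls "
      f"({(loh['loh_class'] == 'CNN_LOH').sum()} copy-neutral)")
print(f"median trunk-LOH fraction: {frac['trunk_loh_fraction'].median():.2f} "
      "(fraction of LOH events shared by all regions)")
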