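"""Neoantigen burden, HLA loss of heterozygosity and escape summaries."""

import pandas as pd

from ithseq.cna_analysis import default_gene_model, gene_level_cna
from ithseq.genomic_ith import classify_trunk_branch_private, mutation_matrix
from ithseq.immune_escape import (
    call_hla_loh, filter_neoantigen_binders, ifng_loss_burden,
    lost_allele_binding_fraction, neoantigen_ith_summary, tumor_hla_loh_status,
)
from ithseq.synthetic_cohort import SimulationConfig, simulate_cohort
from ithseq.variant_filtering import filter_and_rescue

cohort, truth = simulate_cohort(SimulationConfig(n_patients=6, seed=4))

hla_rows, lost_rows = [], []
for pat, b in sorted(cohort.bundles.items()):
    binders = filter_neoantigen_binders(b.neoantigens)
    calls = call_hla_loh(b.hla_allele_cn)
    hla_rows.append(calls)
    lost_rows.append(lost_allele_binding_fraction(binders, calls))
    if pat == "P01":
        kept = filter_and_rescue(b.variants)
        labels = classify_trunk_branch_private(mutation_matrix(kept, b.regions))
        s = neoantigen_ith_summary(binders, labels)
        print(f"P01: {s['n_binders']} predicted binders (IC50 < 500 nM) on "
              f"{s['n_mutations']} mutations; trunk fraction {s['trunk_fraction']:.2f}")

hla = pd.concat(hla_rows, ignore_index=True)
status = tumor_hla_loh_status(hla)
print("HLA-LOH status per tumor:", dict(status.set_index("patient_id")["hla_loh_status"]))
lost_rows = [l for l in lost_rows if len(l)]
lost = pd.concat(lost_rows, ignore_index=True) if lost_rows else pd.DataFrame()
if len(lost):
    print(f"median fraction of binders presented by a lost allele: "
          f"{lost['lost_allele_fraction'].median():.2f}")

gene_calls = gene_level_cna(cohort.segments, default_gene_model())
tbl, corr = ifng_loss_burden(gene_calls)
print(f"IFN-gamma pathway loss vs CNA burden: Spearman rho {corr['rho']:.2f} "
      f"(p={corr['p_value']:.3g}) over {corr['n']} samples")
# A positive rho says tumors losing more genes overall also lose more
# IFN-gamma pathway genes, one plausible route to immune escape.
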