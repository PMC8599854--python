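"""TCR-beta repertoire metrics, overlap and regional sharing."""

import pandas as pd

from ithseq.io_cohort import ADJACENT_LUNG
from ithseq.synthetic_cohort import SimulationConfig, simulate_cohort
from ithseq.tcr_repertoire import (
    pairwise_overlap_table, repertoire_metrics, sharing_classes,
    tumor_vs_adjacent_contrast,
)

cohort, _ = simulate_cohort(SimulationConfig(n_patients=6, seed=12))

tumor_rows, adj_rows = [], []
for pat, b in sorted(cohort.bundles.items()):
    tumor_tables = [t for r, t in sorted(b.repertoires.items()) if r != ADJACENT_LUNG]
    for t in tumor_tables:
        m = repertoire_metrics(t)
        tumor_rows.append({"patient_id": pat, "density": m.density,
                           "richness": m.richness, "clonality": m.clonality})
    m = repertoire_metrics(b.repertoires[ADJACENT_LUNG])
    adj_rows.append({"patient_id": pat, "density": m.density,
                     "richness": m.richness, "clonality": m.clonality})
    if pat == "P01":
        ov = pairwise_overlap_table(tumor_tables)
        sh = sharing_classes(tumor_tables)
        print(f"P01 pairwise overlap (mean): Jaccard {ov['jaccard'].mean():.3f}, "
              f"Morisita-Horn {ov['morisita'].mean():.3f}, "
              f"top-20 shared {ov['top20_shared'].mean():.3f}")
        print(f"P01 clonotype sharing: {sh['shared']:.1%} in all regions, "
              f"{sh['private']:.1%} restricted to one region")

tumor = pd.DataFrame(tumor_rows)
adjacent = pd.DataFrame(adj_rows)
print(f"median tumor density {tumor['density'].median():.4f}, "
      f"richness {tumor['richness'].median():.0f}, "
      f"clonality {tumor['clonality'].median():.4f}")
res = tumor_vs_adjacent_contrast(tumor, adjacent)
print(res.to_string(index=False))
# Tumors are 'colder' than adjacent lung: lower density, richness and
# clonality, tested pairwise per patient.
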