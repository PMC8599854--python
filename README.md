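# ithseq

Multi-region immunogenomic intratumor-heterogeneity (ITH) analysis for
limited-stage small-cell lung cancer cohorts — the full desk-side stack
from per-region somatic calls to survival curves, with a ground-truth
synthetic-cohort generator so every stage is testable without
controlled-access data.

Multi-region studies sequence 2–3 spatially separated pieces of each
resected tumor (whole exome plus TCR-β immunosequencing) and ask two linked
questions: how heterogeneous is the tumor genome between regions, and how
cold or heterogeneous is the T-cell compartment that should be policing it?
`ithseq` implements the quantitative machinery those studies rest on:

- **Variant QC for FFPE exomes** — depth/VAF/population filters, a strict
  LOD > 18 artifact cut, substitution-spectrum QC, and the cross-region
  *rescue* rule (a call failing only on LOD is kept when the identical
  mutation passed in another region of the same tumor).
- **Genomic ITH** — trunk/branch/private labels from the binary
  mutation × region matrix; pairwise mutational Jaccard indices; exhaustive
  Wagner-parsimony trees rooted at the germline; CCF estimation
  `ccf = vaf·(p·c+(1−p)·2)/(p·m)` and BIC-selected Gaussian-mixture clonal
  architecture (clonal = the highest-prevalence cluster).
- **Copy number** — gene-level calls at strict ±0.6 log2 thresholds, CNA
  burden and CNA Jaccard over (gene, direction) events, oncogene-gain
  confirmation against ploidy, and CNN-LOH (A=2,B=0) / CNL-LOH (A=1,B=0)
  classification with trunk/branch status.
- **Immune escape** — IC50 < 500 nM neoantigen binders and their
  trunk/clonal structure, LOH enrichment in neoantigen-associated genes,
  IFN-γ-pathway loss vs CNA burden, a simplified HLA-LOH caller
  (median allele copy < 0.5 and imbalance p < 0.01), and the fraction of
  binders presented by a lost allele.
- **TCR-β repertoire** — density, richness, clonality (1 − Pielou
  evenness); Jaccard / Morisita–Horn / top-20 overlap; regional sharing
  classes; tumor-vs-adjacent-lung contrasts.
- **Mutational signatures** — 96-channel catalogs and deterministic
  forward-selection NNLS refitting against a 30-signature reference, with
  a trunk-vs-nontrunk contrast of the top-5 signature shares.
- **Cohort statistics** — exact/asymptotic Mann–Whitney, Spearman,
  chi-squared without continuity correction, median/positivity
  dichotomization, Kaplan–Meier + log-rank, univariate Cox.

See `docs/methods.md` for models, conventions, parameter defaults and
limitations.

## Worked example

Each script in `examples/` exercises one capability on a small simulated
cohort. For instance:

```bash
$ python examples/03_phylogeny_and_clonality.py
mutation classes: {'trunk': 160, 'branch': 20, 'private': 20}
trunk fraction 0.800 (ground truth 0.800)
mean pairwise mutational Jaccard index: 0.862
parsimony tree, 211 changes (160 on the trunk): (germline:0,((R1:13,R2:12):9,R3:17):160);
CCF clustering chose k=2; clonal fraction 0.81 (mutations in the highest-prevalence cluster)
```

One simulated tumor: 160 of its 200 mutations are shared by all three
regions, and the filtered pipeline recovers that trunk fraction exactly.
The parsimony tree places those 160 on the germline-to-ancestor trunk edge
(the 211 total includes homoplasies forced by noise), and CCF clustering
calls 81% of tumor-level mutations clonal — a genomically homogeneous
tumor, as in the cohorts this package models.

```bash
$ python examples/06_tcr_repertoire.py
P01 pairwise overlap (mean): Jaccard 0.047, Morisita-Horn 0.084, top-20 shared 0.000
P01 clonotype sharing: 1.0% in all regions, 92.2% restricted to one region
median tumor density 0.0160, richness 500, clonality 0.0114
...
```

The same tumors carry a cold, fragmented T-cell repertoire: ~1.6% T-cell
density, clonality ~0.01, and only ~1% of clonotypes found in every region.

A thin CLI mirrors the library for shell use
(`ithseq simulate|validate|qc|ith|cna|escape|tcr|signatures|stats`); each
subcommand reads the documented TSV dialects and writes result tables plus
a manifest.

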