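# Methods

`ithseq` re-implements, as a tested library, the analysis stack used in
multi-region immunogenomic studies of limited-stage small-cell lung cancer
(LS-SCLC): somatic-variant QC tuned for FFPE exomes, trunk/branch/private
phylogenetics, clonal architecture from cancer-cell fractions, gene-level
copy-number and LOH classification, HLA-LOH and neoantigen escape
summaries, TCR-β repertoire metrics, mutational-signature refitting, and
the cohort/survival statistics that tie these together. A synthetic-cohort
generator with recorded ground truth stands in for the controlled-access
patient data, so every stage is testable end to end.

## Variant QC and the rescue rule

Calls are filtered per region with: tumor depth ≥ 20, germline depth ≥ 10,
tumor VAF ≥ 0.02, germline VAF < 0.01, ≥ 4 alt reads, population frequency
< 0.01 in all three databases (ESP6500 / 1000G / ExAC columns), and LOD
strictly > 18 (caller default 6.3). The elevated LOD cut targets formalin
artifacts, which present as low-LOD, low-VAF C>T|G>A transitions; the
substitution-spectrum summary stratified at the LOD cut is the QC readout.
A call failing *only* the LOD rule is rescued when the identical mutation
(chrom, pos, ref, alt — gene not consulted) passed with LOD ≥ 18 in another
region of the same tumor. Tumor-level analysis reuses the same stack with
LOD > 30 and rescues from the region-level pass set. Both thresholds are
`FilterThresholds` fields.

Cancer-gene alterations: a hotspot match, a stopgain/frameshift in a
tumor-suppressor gene, or a nonsynonymous variant with CADD > 20 (missing
CADD conservatively counts as not > 20). TMB is nonsilent mutations
(nonsynonymous, frameshift, stopgain, stoploss) per Mb; the exome footprint
is not a property of the data, so it is exposed as `capture_mb`
(default 30.0).

## Trunk/branch/private structure and phylogenies

Each tumor's mutations form a binary mutation × region matrix. Trunk =
present in all regions, private = exactly one, branch = otherwise;
single-region tumors are all-trunk by convention and flagged as excluded
from ITH summaries. The per-tumor mutational Jaccard index is |∩|/|∪| over
region mutation sets, summarised as the mean over region pairs (the
per-pair table is also emitted).

Phylogenies are Wagner parsimony on the binary matrix with an all-zero
germline root. At study scale (2–3 regions, max 8 enforced) the search is
exhaustive over rooted binary topologies; per character the minimum change
count is computed by Sankoff dynamic programming with the root state fixed
at 0 (reversals allowed). Ties between topologies are broken by the
lexicographically smallest canonical encoding. Mutations are placed on
edges by a delayed (parent-state-preferring) assignment; the trunk edge is
the germline edge. Tests verify agreement with an independent brute-force
oracle that enumerates topologies and internal state assignments
exhaustively.

## CCF and clonal architecture

CCF = VAF · (p·c + (1−p)·2) / (p·m) for purity p, local total copy number c
and multiplicity m. Defaults are m = 1 and c = 2; when the major allele
count exceeds 1 and the implied CCF exceeds 1, m is set to the rounded
implied value capped at the major-allele count (standard practice; the
choice is exposed). The raw value is recorded before clamping to [0, 1].

Tumor-level clonal architecture deliberately simplifies Dirichlet-process
CCF clustering to a 1-D Gaussian mixture with BIC selection over k = 1..5
(`random_state` fixed). Clustering runs on the *raw* CCFs — clamping first
creates a point mass at 1 that the mixture would split into a spurious
spike component. The clonal/subclonal rule is unchanged from field
practice: a mutation is clonal iff it belongs to the cluster with the
highest cellular prevalence (cluster mean). Fewer than 5 mutations fall
back to one flagged cluster. Regions are merged at the count level (sum of
alt and total reads per locus) to emulate merged alignments.

## Copy number and LOH

Gene-level calls use the overlap-length-weighted mean log2 ratio of the
segments touching each gene against strict ±0.6 thresholds (exactly ±0.6 is
neutral). A CNA event is a (gene, direction) pair everywhere, which makes
burden counts and the CNA Jaccard index consistent; tumor-level burden is
the union of events over regions. Oncogene gains are confirmed only when
the integer copy number exceeds the region's overall ploidy. LOH classes
come from the allele counts of the segment covering the gene midpoint (a
deterministic tie-break for genes spanning several segments): (A=2, B=0) is
copy-neutral LOH, (A=1, B=0) copy-loss LOH. An LOH event is trunk iff seen
in every region.

The packaged gene model is a synthetic, programmatically built ~1000-gene
panel on 22 autosomes carrying real symbols for the genes the analyses
reference (TP53, RB1, the IFN-γ pathway panel, oncogene/TSG panel, HLA
loci); any BED-like gene table can be substituted. The default IFN-γ
pathway set (IFNGR1, IFNGR2, JAK1, JAK2, STAT1, IRF1, B2M, IFNG) is a
reconstruction of the usual pathway panel and is config-overridable.

## Immune escape

Predicted peptides are binders iff IC50 < 500 nM (strict). Neoantigens
inherit their mutation's trunk/clonal labels; fractions are over distinct
neoantigen-bearing mutations. LOH enrichment compares, per sample, the
CNN-LOH (or CNL-LOH) fraction among neoantigen-associated genes vs
mutated-but-non-neoantigen genes, with a paired two-sided Wilcoxon test
across samples. The HLA-LOH caller consumes binned allele-specific copy
estimates and applies the published decision rule verbatim — an allele is
lost iff its median binned copy number is < 0.5 *and* the allele-imbalance
p < 0.01 — with a two-sided Mann–Whitney test between the two alleles' bins
as the imbalance test (a rank test is robust to the bin-level noise; the
read-level BAF/logR machinery is out of scope, and calls on fewer than 5
bins are flagged low-confidence). A tumor is trunk-HLA-LOH iff some allele
is lost in every region.

## TCR-β repertoire

Density = templates per nucleated input cell; richness = unique productive
rearrangements R; clonality = 1 − H/ln R with H the Shannon entropy of
productive frequencies renormalised to sum to 1 (natural log, Pielou's
convention; defined as 0 when R = 1). Overlap: Jaccard on rearrangement
sets; the Morisita index is implemented as Morisita–Horn on template counts
(the immunoSEQ convention; scale-invariant); top-20 sharing is the overlap
of the 20 most frequent clonotypes over a denominator of 20 (or the smaller
repertoire's size when below 20), ties broken by rearrangement string.
Nucleotide rearrangement identity is the clonotype unit throughout. The
verbal "shared over total" phrasing of the Jaccard index is read as the
standard |∩|/|∪| (consistent with its name and [0,1] range); the literal
shared/(|A|+|B|) reading is not used. Tumor-vs-adjacent contrasts use a
paired Wilcoxon over patient-matched pairs, falling back to Mann–Whitney
when fewer than 3 pairs exist (recorded in the output).

## Mutational signatures

SNVs are collapsed to the 96 pyrimidine-strand trinucleotide channels
(classes C>A…T>G in order, contexts alphabetical). Refitting is
forward-selection NNLS against a 96×30 reference: at each step the
signature that most reduces the residual norm joins the model; selection
stops when the improvement in the L2 reconstruction error falls below 1e-3;
weights below 0.06 (the conventional reporting cutoff) are zeroed and the
rest renormalised to the pre-cutoff mass. The fit is exactly deterministic.
Trinucleotide-frequency renormalisation between exome and genome space is
unnecessary here because synthetic catalogs are generated directly in
channel space.

The packaged reference is **synthetic** (`signatures_30_synthetic.tsv`,
regenerable via `scripts/build_reference_signatures.py`): 30 profiles from
a fixed seed with domain-shaped anchors (Signature 1 CpG-C>T, Signature 3
broad/weakly structured, Signature 4 C>A-dominant, Signature 5 broad with
T>C enrichment). Every recovery statement in the tests is defined relative
to this packaged matrix; a genuine reference matrix can be passed wherever
`reference` is accepted.

The trunk/nontrunk contrast pools exposures across tumors per compartment,
keeps the top-5 signatures and renormalises; the across-tumor test is a
paired two-sided Wilcoxon on per-tumor shares of a named signature (the
original analysis does not state its test; this choice is ours).

## Cohort and survival statistics

Mann–Whitney is exact for combined n ≤ 20 without ties, otherwise
normal-approximated with tie correction. Spearman uses the t
approximation. Contingency tests are Pearson chi-squared **without**
continuity correction — verified to reproduce printed clinical-table
p-values (0.155 / 0.2025 / 0.0666) from the printed counts, which the
corrected statistic does not. Median dichotomization sends values equal to
the median to "low" (so "high" is strictly above the median);
positivity dichotomization sends 0 to "negative". Kaplan–Meier and the
two-sided log-rank test come from lifelines, as does the univariate Cox fit
(Efron ties); Cox requires ≥ 10 patients, ≥ 5 events and a non-constant
covariate. Because the original figures do not state whether hazard ratios
are per-unit or group-based, the acceptance summary reports per-SD hazard
ratios, labeled as such.

## The synthetic cohort generator

Defaults encode the study conditions: 19 patients, 3 regions per tumor
(optionally one single-region patient), 200 mutations per tumor, trunk
fraction 0.8, tumor depth ~180×/germline ~161× (negative binomial,
dispersion 15), purity 0.5–0.9, clonal CCF 1.0 and subclonal CCFs uniform
on 0.25–0.7 (the floor keeps true subclonal calls above the detectability
thresholds at the simulated depths, so label recovery errors measure the
pipeline rather than sampling dropout). Alt reads are binomial with success
probability p·CCF·m/(p·c+(1−p)·2), m = 1, c = 2. Trunk mutations draw
trinucleotide channels from a Signature-4-dominant mixture (0.62) and
non-trunk from a Signature-3-dominant mixture (0.45), mirroring the
early/late mutational-process contrast. Eight percent of multi-region
mutations get a sub-threshold LOD in one region (exercising rescue), and 25
FFPE-artifact calls per region (low LOD, low VAF, 80% C>T) exercise the
filters; with 2 regions a strict ≥2-region subset does not exist, so all
non-trunk mass is private.

CNA: each tumor draws a lognormal burden multiplier (σ = 0.6) on the
per-gene gain/loss probabilities (0.05 each), giving the strong
between-patient burden variation seen in practice; events are shared by all
regions with probability 0.5 (CNA JI ≈ 0.5–0.65), while planted copy-neutral
LOH is trunk with probability 0.9 (LOH is predominantly early). CNN-LOH is
planted 2× more often in neoantigen-associated genes, and IFN-γ pathway
loss probability (0.25) scales with the tumor's burden multiplier, creating
the positive loss-vs-burden correlation. Segments are gene-aligned (gain
log2 +1, A/B = 3/1; loss −1, 1/0; CNN-LOH 0, 2/0; neutral 0, 1/1; Gaussian
log2 jitter σ = 0.04), so the no-noise mode recovers every planted event
exactly. HLA LOH hits 9/19 of tumors, trunk in 5/9 of those; lost-allele
bins center on 0.2 copies vs 1.0 (σ = 0.06, 20 bins).

Repertoires: Pareto(α = 8) clone sizes over 500 clonotypes with multinomial
template sampling at 4000 templates / 250k input cells reproduce the
observed scale of tumor repertoires (density ≈ 1.6%, richness ≈ 500,
clonality ≈ 0.01); each region draws 30% of its clonotypes from a per-tumor
pool, which yields pairwise Jaccard ≈ 0.05 and ≈ 1% of clonotypes in all
regions. Adjacent-lung samples are generated hotter (2× richness, 3×
templates, α/2) so the tumor-vs-adjacent contrast has a real effect to
find. Survival is exponential proportional hazards on standardised
covariates (default log-hazards −0.3 for TMB, +0.3 for CNA burden;
baseline median 30 months) with independent exponential censoring
calibrated to the requested censored fraction (0.35).

What the generator does **not** emulate: read-level data, indel structure
beyond class labels, subclonal copy-number mixtures within a region,
V/J-gene usage, and between-region purity gradients correlated with
histology. Green tests therefore demonstrate that the estimators recover
the stated generative structure at realistic noise levels — not that any
biological claim about real tumors is reproduced.

## Problem sizes and determinism

Tests and the acceptance summary run at the study's own scale (≤ 20 tumors,
2–3 regions, 200 mutations per tumor, 500-clone repertoires, ~1000-gene
panel), which keeps the full suite around half a minute. All randomness
flows from explicit integer seeds through numpy Generators, so cohorts,
fits and result files are byte-identical across runs and platforms;
`write_results` emits a manifest with row counts and a config hash to make
that checkable.

## Known limitations

The clonal-architecture mixture has no multi-sample joint model, so
mutations shared at different CCFs across regions are clustered only on
merged counts. The Wagner search is exact but exponential — it refuses more
than 8 regions. The HLA-LOH caller assumes its binned copy estimates are
purity/ploidy-adjusted upstream. The synthetic reference signature matrix
shares only coarse structure with the public catalog, so fitted weights on
real catalogs are not comparable to published exposures without swapping in
the real matrix.
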