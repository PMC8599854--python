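"""Synthetic multi-region cohorts with known ground truth.

Generates cohorts in exactly the on-disk/in-memory shapes the pipeline
consumes, with every latent quantity (trunk/branch/private labels, CCFs,
CNA and LOH events, HLA losses, shared clonotypes, hazard coefficients)
recorded in a :class:`GroundTruth` object so each downstream stage can be
tested against truth without any external data.

Observation models
------------------
* Mutations: a ``trunk_fraction`` of each tumor's mutations is placed in
  all regions (CCF = 1); the remainder is split between *branch* (a strict
  subset of >= 2 regions) and *private* (one region) with subclonal CCFs.
  Per region, read depth is negative-binomial around a configurable mean
  (default 180x, typical of FFPE exomes) and alt reads are binomial with
  success probability purity*CCF*multiplicity / (purity*CN + (1-purity)*2),
  with multiplicity 1 and local CN 2 by default.
* Trinucleotide channels of trunk vs non-trunk mutations are drawn from
  separate 30-signature mixtures (defaults: smoking-signature-dominant
  trunk, DSB-repair-signature-dominant branch, mirroring early-vs-late
  mutational processes in smokers' tumors).
* A fraction of multi-region mutations receives a sub-threshold LOD score
  in one region, and per-region FFPE artifact calls (low LOD, low VAF,
  C>T-skewed) are injected, so the QC filters and the rescue rule do real
  work on defaults.
* CNAs are gene-level events (gain/loss) shared by all regions with
  probability ``cna_trunk_fraction``; losses carry (A=1, B=0) alleles,
  planted copy-neutral LOH (A=2, B=0) is enriched in neoantigen-associated
  genes; IFN-gamma pathway losses scale with a region's event burden.
* Repertoires: clone sizes are Pareto(``clone_size_alpha``) (smaller alpha
  = heavier tail = higher clonality); each tumor region draws a
  ``shared_clone_fraction`` of its clonotypes from a per-tumor pool.
* Survival: exponential proportional hazards on standardised covariates
  with independent exponential censoring.

``noise=False`` switches every observation model to its deterministic
mean, so ground truth is reproduced exactly through the full pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cna_analysis import IFNG_PATHWAY_GENES, default_gene_model
from .io_cohort import ADJACENT_LUNG, ClonotypeTable, Cohort, TumorBundle, VARIANT_COLUMNS
from .mutational_signatures import CHANNELS, channel_to_tnc, load_reference

DEFAULT_TRUNK_MIX = {
    "Signature 4": 0.62, "Signature 1": 0.12, "Signature 5": 0.10,
    "Signature 15": 0.10, "Signature 3": 0.06,
}
DEFAULT_BRANCH_MIX = {
    "Signature 3": 0.45, "Signature 4": 0.29, "Signature 1": 0.08,
    "Signature 5": 0.08, "Signature 15": 0.10,
}

_HLA_POOL = {
    "HLA-A": ["A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02"],
    "HLA-B": ["B*07:02", "B*08:01", "B*15:01", "B*35:01", "B*44:02"],
    "HLA-C": ["C*03:04", "C*04:01", "C*07:01", "C*07:02", "C*12:03"],
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 19 tumors, 3 regions, 200 mutations/tumor,
    80% trunk, 180x depth; see the class body for every knob."""

    n_patients: int = 19
    regions_per_tumor: int = 3
    include_single_region_patient: bool = False
    mutations_per_tumor: int = 200
    trunk_fraction: float = 0.8
    purity_range: tuple[float, float] = (0.5, 0.9)
    clonal_ccf: float = 1.0
    subclonal_ccf_range: tuple[float, float] = (0.25, 0.7)
    trunk_signature_mix: dict = field(default_factory=lambda: dict(DEFAULT_TRUNK_MIX))
    branch_signature_mix: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_MIX))
    mean_depth: float = 180.0
    mean_normal_depth: float = 161.0
    depth_dispersion: float = 15.0  # negative-binomial size parameter
    lod_low_fraction: float = 0.08
    ffpe_artifacts_per_region: int = 25
    segments_per_region: int = 44
    p_gene_gain: float = 0.05
    p_gene_loss: float = 0.05
    burden_dispersion: float = 0.6  # lognormal sigma of the per-tumor CNA rate
    cna_trunk_fraction: float = 0.5
    p_cnn_loh: float = 0.04
    cnn_loh_neo_enrichment: float = 2.0
    cnn_loh_trunk_fraction: float = 0.9  # LOH is mostly an early, shared event
    p_ifng_loss: float = 0.25
    ifng_burden_coupling: float = 1.0
    p_hla_loh: float = 9 / 19
    p_hla_trunk_given_loh: float = 5 / 9
    hla_bins: int = 20
    p_neoantigen: float = 0.45
    lost_allele_binding_bias: float = 0.5
    clone_size_alpha: float = 8.0
    shared_clone_fraction: float = 0.3
    repertoire_size: int = 500
    total_templates: int = 4000
    input_cells: int = 250_000
    survival_betas: dict = field(default_factory=lambda: {"tmb": -0.3, "cna_burden": 0.3})
    baseline_median_os: float = 30.0
    censoring_rate: float = 0.35
    noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "trunk_fraction": self.trunk_fraction,
            "lod_low_fraction": self.lod_low_fraction,
            "cna_trunk_fraction": self.cna_trunk_fraction,
            "p_gene_gain": self.p_gene_gain, "p_gene_loss": self.p_gene_loss,
            "p_cnn_loh": self.p_cnn_loh, "p_ifng_loss": self.p_ifng_loss,
            "p_hla_loh": self.p_hla_loh, "p_neoantigen": self.p_neoantigen,
            "shared_clone_fraction": self.shared_clone_fraction,
            "censoring_rate": self.censoring_rate,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, mix in (("trunk_signature_mix", self.trunk_signature_mix),
                          ("branch_signature_mix", self.branch_signature_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.clone_size_alpha <= 0:
            raise ValueError("clone_size_alpha must be positive")
        if self.regions_per_tumor < 2 and self.trunk_fraction < 1:
            raise ValueError(
                "single-region tumors cannot carry branch/private mutations; "
                "set trunk_fraction=1 or regions_per_tumor >= 2"
            )
        if self.repertoire_size < 1:
            raise ValueError("repertoire_size must be >= 1")


@dataclass
class GroundTruth:
    mutations: pd.DataFrame      # patient, key, compartment, ccf, clonal, channel
    cna_events: pd.DataFrame     # patient, gene, direction, trunk, regions
    loh_events: pd.DataFrame     # patient, gene, loh_class, trunk, regions
    hla_loh: pd.DataFrame        # patient, allele, trunk, regions
    artifacts: pd.DataFrame      # injected FFPE artifact calls
    shared_clones: dict          # patient -> tumor clone pool
    survival_betas: dict
    config: dict

    def trunk_fraction(self, patient: str) -> float:
        m = self.mutations[self.mutations["patient_id"] == patient]
        return float((m["compartment"] == "trunk").mean())


# ---------------------------------------------------------------------------
# helpers

def _nb_depth(rng, mean, size, dispersion, noise):
    if not noise:
        return np.full(size, int(round(mean)))
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size) + 1


def _random_peptide(rng, length):
    return "".join(rng.choice(list(_AA), size=length))


def _random_rearrangement(rng):
    return "".join(rng.choice(list(_NT), size=30))


def simulate_repertoire(
    config: SimulationConfig,
    pool: list[str],
    patient_id: str,
    region_id: str,
    rng: np.random.Generator,
    alpha: float | None = None,
    richness: int | None = None,
    total_templates: int | None = None,
    input_cells: int | None = None,
) -> ClonotypeTable:
    """One sample's clonotype table.

    ``shared_clone_fraction`` of the clonotypes is drawn (without
    replacement) from the per-tumor ``pool``; the rest are sample-unique.
    Clone sizes are Pareto(alpha) (heavy-tailed for small alpha); template
    counts are multinomial at the sample's total template count.
    """
    alpha = config.clone_size_alpha if alpha is None else alpha
    if alpha <= 0:
        raise ValueError("clone size exponent must be positive")
    R = config.repertoire_size if richness is None else richness
    total = config.total_templates if total_templates is None else total_templates
    cells = config.input_cells if input_cells is None else input_cells
    n_shared = int(round(config.shared_clone_fraction * R))
    n_shared = min(n_shared, len(pool))
    shared = list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
    unique = [_random_rearrangement(rng) for _ in range(R - n_shared)]
    clones = shared + unique
    sizes = rng.pareto(alpha, size=R) + 1.0
    p = sizes / sizes.sum()
    templates = rng.multinomial(max(total, R), p)
    templates = np.maximum(templates, 1)  # every listed clonotype was observed
    freq = templates / templates.sum()
    rows = pd.DataFrame({
        "rearrangement": clones,
        "templates": templates.astype(int),
        "productive_frequency": freq,
    }).sort_values("templates", ascending=False, ignore_index=True)
    return ClonotypeTable(patient_id, region_id, rows, int(templates.sum()), int(cells))


def simulate_survival(
    covariates: pd.DataFrame,
    betas: dict[str, float],
    censoring_rate: float,
    seed: int,
    baseline_median: float = 30.0,
) -> pd.DataFrame:
    """Exponential proportional-hazards event times with independent censoring.

    Covariates are standardised before entering the linear predictor;
    censoring times are exponential with rate chosen so the expected
    censored fraction equals ``censoring_rate``.
    """
    if censoring_rate < 0:
        raise ValueError("censoring_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(covariates))
    for name, beta in betas.items():
        x = covariates[name].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        lp += beta * z
    base_rate = np.log(2) / baseline_median
    times = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    if censoring_rate >= 1:
        event = np.zeros(len(times), dtype=int)
        obs = times
    elif censoring_rate == 0:
        event = np.ones(len(times), dtype=int)
        obs = times
    else:
        c_rate = base_rate * censoring_rate / (1 - censoring_rate)
        censor = rng.exponential(1.0 / c_rate, size=len(times))
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    return pd.DataFrame({
        "patient_id": covariates["patient_id"].values,
        "os_months": np.round(obs, 2),
        "os_event": event,
    })


# ---------------------------------------------------------------------------
# main generator

def simulate_cohort(config: SimulationConfig | None = None):
    """Generate (cohort, ground_truth); deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference = load_reference()
    genes = default_gene_model()
    gene_rows = genes.set_index("gene")
    gene_names = genes["gene"].tolist()
    noise = config.noise

    trunk_probs = _mix_to_channel_probs(config.trunk_signature_mix, reference)
    branch_probs = _mix_to_channel_probs(config.branch_signature_mix, reference)

    bundles: dict[str, TumorBundle] = {}
    gt_mut, gt_cna, gt_loh, gt_hla, gt_art = [], [], [], [], []
    shared_pools: dict[str, list] = {}
    covar_rows = []

    n_pat = config.n_patients
    for pi in range(n_pat):
        pat = f"P{pi + 1:02d}"
        n_regions = config.regions_per_tumor
        if config.include_single_region_patient and pi == n_pat - 1:
            n_regions = 1
        regions = [f"R{j + 1}" for j in range(n_regions)]
        purity = {
            r: (np.mean(config.purity_range) if not noise
                else float(rng.uniform(*config.purity_range)))
            for r in regions
        }
        ploidy = {r: 2.0 for r in regions}

        variants, mut_truth = _simulate_mutations(
            config, rng, pat, regions, purity, trunk_probs, branch_probs, gene_names)
        gt_mut.extend(mut_truth)

        if noise and config.ffpe_artifacts_per_region:
            art = _simulate_artifacts(config, rng, pat, regions, gene_names)
            variants = pd.concat([variants, art], ignore_index=True)
            gt_art.append(art)

        mutated_genes = set(variants["gene"])
        segments, cna_truth, loh_truth, neo_gene_pool = _simulate_segments(
            config, rng, pat, regions, genes, gene_rows, mut_truth)
        gt_cna.extend(cna_truth)
        gt_loh.extend(loh_truth)

        genotype = sorted(
            a for g in _HLA_POOL
            for a in rng.choice(_HLA_POOL[g], size=2, replace=False)
        )
        hla_cn, hla_truth = _simulate_hla(config, rng, pat, regions, genotype)
        gt_hla.extend(hla_truth)
        lost_alleles = {h["allele"] for h in hla_truth}

        neoantigens = _simulate_neoantigens(
            config, rng, pat, variants, mut_truth, genotype, lost_alleles, neo_gene_pool)

        pool = [_random_rearrangement(rng) for _ in range(config.repertoire_size)]
        shared_pools[pat] = pool
        repertoires = {}
        for r in regions:
            repertoires[r] = simulate_repertoire(config, pool, pat, r, rng)
        repertoires[ADJACENT_LUNG] = simulate_repertoire(
            config, [], pat, ADJACENT_LUNG, rng,
            alpha=config.clone_size_alpha / 2,
            richness=config.repertoire_size * 2,
            total_templates=config.total_templates * 3,
        )

        bundles[pat] = TumorBundle(
            patient_id=pat, regions=regions, variants=variants, segments=segments,
            purity=purity, ploidy=ploidy, hla_genotype=genotype,
            hla_allele_cn=hla_cn, neoantigens=neoantigens, repertoires=repertoires,
        )
        n_nonsilent = int(variants[variants["func_class"].isin(
            ("nonsynonymous", "frameshift", "stopgain", "stoploss")
        )].drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).shape[0])
        n_cna = len([e for e in cna_truth])
        covar_rows.append({"patient_id": pat, "tmb": n_nonsilent / 30.0, "cna_burden": n_cna})

    covariates = pd.DataFrame(covar_rows)
    clinical = simulate_survival(
        covariates, config.survival_betas, config.censoring_rate,
        seed=int(rng.integers(2**31)), baseline_median=config.baseline_median_os)
    for pat, b in bundles.items():
        row = clinical[clinical["patient_id"] == pat].iloc[0]
        b.clinical = {
            "patient_id": pat,
            "os_months": float(row["os_months"]),
            "os_event": int(row["os_event"]),
            "stage": str(rng.choice(["I", "II", "III"], p=[0.45, 0.3, 0.25])),
            "age": int(rng.integers(38, 84)),
            "sex": str(rng.choice(["M", "F"], p=[0.83, 0.17])),
            "smoking": str(rng.choice(["smoker", "never"], p=[0.76, 0.24])),
            "tumor_size_cm": float(np.round(rng.lognormal(np.log(2.8), 0.35), 1)),
        }

    truth = GroundTruth(
        mutations=pd.DataFrame(gt_mut),
        cna_events=pd.DataFrame(gt_cna, columns=["patient_id", "gene", "direction", "trunk", "regions"]),
        loh_events=pd.DataFrame(gt_loh, columns=["patient_id", "gene", "loh_class", "trunk", "regions"]),
        hla_loh=pd.DataFrame(gt_hla, columns=["patient_id", "gene", "allele", "trunk", "regions"]),
        artifacts=pd.concat(gt_art, ignore_index=True) if gt_art else pd.DataFrame(columns=VARIANT_COLUMNS),
        shared_clones=shared_pools,
        survival_betas=dict(config.survival_betas),
        config=asdict(config),
    )
    return Cohort(bundles), truth


def _mix_to_channel_probs(mix: dict[str, float], reference: pd.DataFrame) -> np.ndarray:
    probs = np.zeros(96)
    for sig, w in mix.items():
        probs += w * reference[sig].to_numpy()
    return probs / probs.sum()


def _simulate_mutations(config, rng, pat, regions, purity, trunk_probs, branch_probs,
                        gene_names):
    n = config.mutations_per_tumor
    n_regions = len(regions)
    n_trunk = int(round(n * config.trunk_fraction))
    n_rest = n - n_trunk
    if n_regions >= 3:
        n_branch = n_rest // 2
    else:
        n_branch = 0
    n_private = n_rest - n_branch

    compartments = (["trunk"] * n_trunk + ["branch"] * n_branch + ["private"] * n_private)
    rows, truth = [], []
    used_pos = set()
    for mi, comp in enumerate(compartments):
        gene = str(rng.choice(gene_names))
        chrom = f"chr{rng.integers(1, 23)}"
        while True:
            pos = int(rng.integers(1, 50_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        probs = trunk_probs if comp == "trunk" else branch_probs
        channel = CHANNELS[int(rng.choice(96, p=probs))]
        tnc = channel_to_tnc(channel)
        ref, alt = tnc[1], tnc[5]
        func_class = str(rng.choice(
            ["nonsynonymous", "synonymous", "stopgain", "frameshift", "other"],
            p=[0.70, 0.10, 0.08, 0.07, 0.05]))
        cadd = float(np.round(rng.uniform(0, 40), 2)) if func_class != "synonymous" else np.nan
        if comp == "trunk":
            present = list(regions)
            ccf = config.clonal_ccf
        elif comp == "branch":
            k = int(rng.integers(2, n_regions))  # strict subset, >= 2
            present = sorted(rng.choice(regions, size=k, replace=False))
            ccf = float(rng.uniform(*config.subclonal_ccf_range))
        else:
            present = [str(rng.choice(regions))]
            ccf = float(rng.uniform(*config.subclonal_ccf_range))

        # low-LOD region assignment only where rescue is possible
        low_lod_region = None
        if (config.noise and len(present) >= 2
                and rng.random() < config.lod_low_fraction):
            low_lod_region = str(rng.choice(present))

        for r in present:
            depth = int(_nb_depth(rng, config.mean_depth, 1, config.depth_dispersion,
                                  config.noise)[0])
            p_alt = purity[r] * ccf / (purity[r] * 2 + (1 - purity[r]) * 2)
            alt_reads = (int(rng.binomial(depth, p_alt)) if config.noise
                         else int(round(depth * p_alt)))
            alt_reads = max(alt_reads, 4)  # detectability floor for true calls
            n_depth = int(_nb_depth(rng, config.mean_normal_depth, 1,
                                    config.depth_dispersion, config.noise)[0])
            lod = (float(np.round(rng.uniform(5, 17.5), 2)) if r == low_lod_region
                   else float(np.round(rng.uniform(31, 120), 2)))
            rows.append({
                "patient_id": pat, "region_id": r, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "gene": gene, "func_class": func_class,
                "t_depth": depth, "n_depth": n_depth, "t_alt": alt_reads,
                "t_vaf": round(alt_reads / depth, 6), "n_vaf": 0.0, "lod": lod,
                "cadd": cadd, "popfreq_esp": 0.0, "popfreq_1kg": 0.0,
                "popfreq_exac": 0.0, "tnc": tnc,
            })
        truth.append({
            "patient_id": pat, "key": f"{chrom}:{pos}:{ref}>{alt}", "gene": gene,
            "compartment": comp, "ccf": ccf, "clonal": comp == "trunk",
            "channel": channel, "regions": ",".join(present),
            "func_class": func_class,
        })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS), truth


def _simulate_artifacts(config, rng, pat, regions, gene_names):
    """FFPE-like artifact calls: private, low LOD, low VAF, C>T-skewed."""
    rows = []
    ct_channels = [c for c in CHANNELS if c[2:5] == "C>T"]
    for r in regions:
        for _ in range(config.ffpe_artifacts_per_region):
            channel = str(rng.choice(ct_channels)) if rng.random() < 0.8 else \
                str(rng.choice(CHANNELS))
            tnc = channel_to_tnc(channel)
            chrom = f"chr{rng.integers(1, 23)}"
            pos = int(rng.integers(50_000_001, 60_000_000))  # outside true-call range
            depth = int(_nb_depth(rng, config.mean_depth, 1, config.depth_dispersion, True)[0])
            vaf = float(rng.uniform(0.02, 0.09))
            rows.append({
                "patient_id": pat, "region_id": r, "chrom": chrom, "pos": pos,
                "ref": tnc[1], "alt": tnc[5], "gene": str(rng.choice(gene_names)),
                "func_class": "nonsynonymous", "t_depth": depth,
                "n_depth": int(_nb_depth(rng, config.mean_normal_depth, 1,
                                         config.depth_dispersion, True)[0]),
                "t_alt": max(int(round(vaf * depth)), 4), "t_vaf": round(vaf, 6),
                "n_vaf": 0.0, "lod": float(np.round(rng.uniform(2, 15), 2)),
                "cadd": np.nan, "popfreq_esp": 0.0, "popfreq_1kg": 0.0,
                "popfreq_exac": 0.0, "tnc": tnc,
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _simulate_segments(config, rng, pat, regions, genes, gene_rows, mut_truth):
    """Gene-aligned segments with planted gain/loss/CNN-LOH events."""
    noise = config.noise
    mutated = {m["gene"] for m in mut_truth}
    neo_pool = {m["gene"] for m in mut_truth
                if m["func_class"] == "nonsynonymous" and rng.random() < config.p_neoantigen}

    # per-tumor CNA rate multiplier: burden varies substantially between
    # patients, and the IFN-gamma loss probability scales with it
    burden_mult = float(rng.lognormal(0.0, config.burden_dispersion)) if config.noise else 1.0
    p_gain = min(config.p_gene_gain * burden_mult, 0.3)
    p_loss = min(config.p_gene_loss * burden_mult, 0.3)
    events = []  # (gene, kind) kind in gain/loss/cnn_loh
    for gene in genes["gene"]:
        u = rng.random()
        if u < p_gain:
            events.append((gene, "gain"))
        elif u < p_gain + p_loss:
            events.append((gene, "loss"))
        else:
            p_cnn = config.p_cnn_loh * (
                config.cnn_loh_neo_enrichment if gene in neo_pool else 1.0)
            if gene in mutated and rng.random() < min(p_cnn, 1.0):
                events.append((gene, "cnn_loh"))
    for gene in IFNG_PATHWAY_GENES:
        if any(g == gene for g, _ in events):
            continue
        p = config.p_ifng_loss * (burden_mult ** config.ifng_burden_coupling)
        if rng.random() < min(p, 1.0):
            events.append((gene, "loss"))

    cna_truth, loh_truth = [], []
    event_regions = {}
    for gene, kind in events:
        p_trunk = (config.cnn_loh_trunk_fraction if kind == "cnn_loh"
                   else config.cna_trunk_fraction)
        if len(regions) == 1 or rng.random() < p_trunk:
            present = list(regions)
        else:
            k = int(rng.integers(1, len(regions)))
            present = sorted(rng.choice(regions, size=k, replace=False))
        event_regions[(gene, kind)] = present
        trunk = len(present) == len(regions)
        if kind in ("gain", "loss"):
            cna_truth.append({"patient_id": pat, "gene": gene, "direction": kind,
                              "trunk": trunk, "regions": ",".join(present)})
        if kind == "cnn_loh":
            loh_truth.append({"patient_id": pat, "gene": gene, "loh_class": "CNN_LOH",
                              "trunk": trunk, "regions": ",".join(present)})
        if kind == "loss":
            loh_truth.append({"patient_id": pat, "gene": gene, "loh_class": "CNL_LOH",
                              "trunk": trunk, "regions": ",".join(present)})

    seg_rows = []
    log2_sd = 0.04 if noise else 0.0
    for r in regions:
        for chrom, gsub in genes.groupby("chrom"):
            gsub = gsub.sort_values("start")
            chrom_end = int(gsub["end"].max()) + 100_000
            cursor = 1
            kinds_by_gene = {gene: k for (gene, k), pres in event_regions.items()
                             if r in pres}
            for _, g in gsub.iterrows():
                kind = kinds_by_gene.get(g["gene"])
                if kind is None:
                    continue
                if g["start"] > cursor:
                    seg_rows.append(_segment(pat, r, chrom, cursor, g["start"] - 1,
                                             0.0, 1, 1, rng, log2_sd))
                log2, a, b = {
                    "gain": (1.0, 3, 1), "loss": (-1.0, 1, 0), "cnn_loh": (0.0, 2, 0),
                }[kind]
                seg_rows.append(_segment(pat, r, chrom, int(g["start"]), int(g["end"]),
                                         log2, a, b, rng, log2_sd))
                cursor = int(g["end"]) + 1
            if cursor <= chrom_end:
                seg_rows.append(_segment(pat, r, chrom, cursor, chrom_end,
                                         0.0, 1, 1, rng, log2_sd))
    segments = pd.DataFrame(
        seg_rows,
        columns=["patient_id", "region_id", "chrom", "start", "end", "log2",
                 "a_count", "b_count"],
    )
    return segments, cna_truth, loh_truth, neo_pool


def _segment(pat, reg, chrom, start, end, log2, a, b, rng, sd):
    jitter = float(rng.normal(0, sd)) if sd else 0.0
    return {"patient_id": pat, "region_id": reg, "chrom": chrom, "start": start,
            "end": end, "log2": round(log2 + jitter, 4), "a_count": a, "b_count": b}


def _simulate_hla(config, rng, pat, regions, genotype):
    """Binned allele-specific HLA copy estimates, with optional planted LOH."""
    noise = config.noise
    has_loh = rng.random() < config.p_hla_loh
    lost_allele, present = None, []
    if has_loh:
        lost_allele = str(rng.choice(genotype))
        if len(regions) == 1 or rng.random() < config.p_hla_trunk_given_loh:
            present = list(regions)
        else:
            k = int(rng.integers(1, len(regions)))
            present = sorted(rng.choice(regions, size=k, replace=False))
    rows = []
    for r in regions:
        for allele in genotype:
            gene = "HLA-" + allele.split("*")[0]
            lost_here = allele == lost_allele and r in present
            center = 0.2 if lost_here else 1.0
            for b in range(config.hla_bins):
                cn = center if not noise else float(rng.normal(center, 0.06))
                rows.append({"patient_id": pat, "region_id": r, "gene": gene,
                             "allele": allele, "bin": b, "cn": round(max(cn, 0.0), 4)})
    truth = []
    if has_loh:
        truth.append({"patient_id": pat, "gene": "HLA-" + lost_allele.split("*")[0],
                      "allele": lost_allele, "trunk": len(present) == len(regions),
                      "regions": ",".join(present)})
    return pd.DataFrame(rows), truth


def _simulate_neoantigens(config, rng, pat, variants, mut_truth, genotype,
                          lost_alleles, neo_gene_pool):
    rows = []
    for m in mut_truth:
        if m["func_class"] != "nonsynonymous" or m["gene"] not in neo_gene_pool:
            continue
        chrom, rest = m["key"].split(":", 1)
        pos, change = rest.split(":")
        ref, alt = change.split(">")
        n_pep = int(rng.integers(1, 3))
        for _ in range(n_pep):
            if lost_alleles and rng.random() < config.lost_allele_binding_bias:
                allele = str(rng.choice(sorted(lost_alleles)))
            else:
                allele = str(rng.choice(genotype))
            binder = rng.random() < 0.75
            ic50 = (float(np.round(10 ** rng.uniform(0.7, 2.69), 1)) if binder
                    else float(np.round(rng.uniform(500, 5000), 1)))
            rows.append({
                "patient_id": pat, "chrom": chrom, "pos": int(pos), "ref": ref,
                "alt": alt, "gene": m["gene"],
                "peptide": _random_peptide(rng, int(rng.integers(9, 11))),
                "allele": allele, "ic50_nm": ic50,
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "chrom", "pos", "ref", "alt", "gene", "peptide", "allele", "ic50_nm",
    ])
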