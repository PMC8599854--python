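"""Neoantigen and immune-escape summaries.

Covers the read-outs used to ask whether a tumor has genomic routes around
T-cell recognition: predicted neoantigen burden and its trunk/clonal
structure, enrichment of LOH in neoantigen-associated genes, copy-number
loss of IFN-gamma pathway genes versus global CNA burden, a simplified
allele-level HLA-LOH caller, and the fraction of predicted binders whose
presenting HLA allele has been lost.

The HLA-LOH caller consumes precomputed binned allele-specific copy
estimates (read-level BAF/logR machinery is out of scope) but applies the
published decision rule verbatim: an allele is lost iff the median binned
copy number is < 0.5 and a two-sided allele-imbalance test between the two
alleles' bins gives p < 0.01. The rank-based Mann-Whitney test is used for
the imbalance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna_analysis import IFNG_PATHWAY_GENES

BINDER_IC50_NM = 500.0
HLA_LOSS_CN = 0.5
HLA_LOSS_P = 0.01


def filter_neoantigen_binders(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep predicted peptides with IC50 strictly below 500 nM."""
    if len(calls) == 0:
        return calls.copy()
    return calls[calls["ic50_nm"] < BINDER_IC50_NM].copy()


def neoantigen_ith_summary(
    binders: pd.DataFrame, mutation_labels: pd.DataFrame
) -> dict:
    """Trunk/clonal structure of the neoantigen-bearing mutations of one tumor.

    ``mutation_labels`` is indexed by mutation key ("chrom:pos:ref>alt")
    with a ``label`` column (trunk/branch/private) and optionally a
    ``clonal`` boolean column. Fractions are over distinct
    neoantigen-bearing mutations; a binder whose mutation has no label is
    an error naming the key.
    """
    if len(binders) == 0:
        return {"n_binders": 0, "n_mutations": 0,
                "trunk_fraction": float("nan"), "clonal_fraction": float("nan")}
    keys = (
        binders["chrom"].astype(str) + ":" + binders["pos"].astype(str)
        + ":" + binders["ref"].astype(str) + ">" + binders["alt"].astype(str)
    )
    distinct = pd.unique(keys)
    missing = [k for k in distinct if k not in mutation_labels.index]
    if missing:
        raise KeyError(f"binder mutation(s) without ITH label: {missing[:5]}")
    labels = mutation_labels.loc[distinct]
    out = {
        "n_binders": int(len(binders)),
        "n_mutations": int(len(distinct)),
        "trunk_fraction": float((labels["label"] == "trunk").mean()),
    }
    out["clonal_fraction"] = (
        float(labels["clonal"].mean()) if "clonal" in labels.columns else float("nan")
    )
    return out


def loh_enrichment_comparison(
    loh_calls: pd.DataFrame,
    mutated_genes: dict[str, set],
    neoantigen_genes: dict[str, set],
    loh_class: str = "CNN_LOH",
) -> tuple[pd.DataFrame, dict]:
    """Is LOH more common in neoantigen-associated genes?

    Per sample (patient, region): the fraction of neoantigen-associated
    genes with the given LOH class, and the same fraction among
    mutated-but-non-neoantigen genes. Gene sets are keyed by patient.
    Across samples the two fractions are compared with a two-sided paired
    Wilcoxon signed-rank test.
    """
    rows = []
    loh_idx = loh_calls.set_index(["patient_id", "region_id"])
    for (pat, reg), grp in loh_calls.groupby(["patient_id", "region_id"]):
        neo = neoantigen_genes.get(pat, set())
        mut = mutated_genes.get(pat, set()) - neo
        with_class = set(grp[grp["loh_class"] == loh_class]["gene"])
        row = {"patient_id": pat, "region_id": reg}
        row["neo_fraction"] = len(neo & with_class) / len(neo) if neo else np.nan
        row["other_fraction"] = len(mut & with_class) / len(mut) if mut else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id", "region_id", "neo_fraction", "other_fraction"])
    paired = df.dropna(subset=["neo_fraction", "other_fraction"])
    if len(paired) == 0:
        test = {"p_value": float("nan"), "n_pairs": 0}
    elif np.allclose(paired["neo_fraction"], paired["other_fraction"]):
        test = {"p_value": 1.0, "n_pairs": int(len(paired))}
    else:
        res = stats.wilcoxon(paired["neo_fraction"], paired["other_fraction"])
        test = {"p_value": float(res.pvalue), "n_pairs": int(len(paired))}
    return df, test


def ifng_loss_burden(
    gene_calls: pd.DataFrame,
    ifng_genes: tuple[str, ...] = IFNG_PATHWAY_GENES,
    burden: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """IFN-gamma pathway loss counts per sample and their correlation with
    total CNA burden.

    ``gene_calls`` is the gene-level CNA table; ``burden`` (patient_id,
    region_id, cna_burden) defaults to counting non-neutral calls in the
    same table. Returns the per-sample table and a Spearman correlation
    summary (rho NaN-flagged when undefined, e.g. no losses anywhere).
    """
    if not ifng_genes:
        raise ValueError("empty IFN-gamma gene set")
    rows = []
    for (pat, reg), grp in gene_calls.groupby(["patient_id", "region_id"]):
        n_loss = int(((grp["state"] == "loss") & grp["gene"].isin(ifng_genes)).sum())
        total = int((grp["state"] != "neutral").sum())
        rows.append({
            "patient_id": pat, "region_id": reg,
            "ifng_loss_count": n_loss, "cna_burden": total,
        })
    df = pd.DataFrame(rows, columns=["patient_id", "region_id", "ifng_loss_count", "cna_burden"])
    if burden is not None:
        df = df.drop(columns=["cna_burden"]).merge(
            burden[burden["region_id"] != "tumor"], on=["patient_id", "region_id"]
        )
    if df["ifng_loss_count"].nunique() <= 1 or df["cna_burden"].nunique() <= 1:
        corr = {"rho": float("nan"), "p_value": float("nan"), "n": int(len(df)),
                "flag": "undefined"}
    else:
        rho, p = stats.spearmanr(df["ifng_loss_count"], df["cna_burden"])
        corr = {"rho": float(rho), "p_value": float(p), "n": int(len(df)), "flag": ""}
    return df, corr


@dataclass
class HlaLohCall:
    patient_id: str
    region_id: str
    allele: str
    median_allele_cn: float
    p_value: float
    lost: bool
    low_confidence: bool = False


def call_hla_loh(allele_cn: pd.DataFrame, min_bins: int = 5) -> pd.DataFrame:
    """Allele-level HLA-LOH calls from binned copy estimates.

    ``allele_cn`` columns: patient_id, region_id, gene (HLA locus), allele,
    cn (one row per bin). Per (region, allele): the median binned copy
    number and a two-sided Mann-Whitney allele-imbalance p between the two
    alleles of the same locus; lost iff median < 0.5 and p < 0.01. Fewer
    than ``min_bins`` bins flags the call low-confidence. Homozygous loci
    (a single distinct allele) are not callable and are skipped.
    """
    rows = []
    for (pat, reg, gene), grp in allele_cn.groupby(["patient_id", "region_id", "gene"]):
        alleles = sorted(grp["allele"].unique())
        if len(alleles) != 2:
            continue
        bins = {al: grp[grp["allele"] == al]["cn"].to_numpy(dtype=float) for al in alleles}
        pooled = np.concatenate(list(bins.values()))
        if np.ptp(pooled) == 0:  # identical constant bins: no imbalance
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(
                bins[alleles[0]], bins[alleles[1]], alternative="two-sided"
            ).pvalue)
        for al in alleles:
            med = float(np.median(bins[al]))
            rows.append({
                "patient_id": pat, "region_id": reg, "gene": gene, "allele": al,
                "median_allele_cn": med, "p_value": p,
                "lost": bool(med < HLA_LOSS_CN and p < HLA_LOSS_P),
                "low_confidence": bool(min(len(b) for b in bins.values()) < min_bins),
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", "gene", "allele", "median_allele_cn",
        "p_value", "lost", "low_confidence",
    ])


def tumor_hla_loh_status(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor HLA-LOH label: 'trunk' iff some allele is lost in every
    region, 'branch' if lost somewhere but not everywhere, 'none' otherwise."""
    rows = []
    for pat, grp in calls.groupby("patient_id"):
        regions = grp["region_id"].nunique()
        status = "none"
        by_allele = grp.groupby(["gene", "allele"])["lost"].agg(["sum", "count"])
        lost_any = by_allele["sum"] > 0
        if lost_any.any():
            trunk = ((by_allele["sum"] == regions) & (by_allele["count"] == regions)).any()
            status = "trunk" if trunk else "branch"
        rows.append({"patient_id": pat, "hla_loh_status": status})
    return pd.DataFrame(rows, columns=["patient_id", "hla_loh_status"])


def lost_allele_binding_fraction(
    binders: pd.DataFrame, hla_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fraction of predicted binders presented by a lost allele.

    Samples without any lost allele are excluded from the output. Binder
    tables carry an ``allele`` column with the presenting class-I allele.
    """
    rows = []
    lost = hla_calls[hla_calls["lost"]]
    for (pat, reg), grp in lost.groupby(["patient_id", "region_id"]):
        lost_alleles = set(grp["allele"])
        sample_binders = binders[binders["patient_id"] == pat]
        if len(sample_binders) == 0:
            continue
        frac = float(sample_binders["allele"].isin(lost_alleles).mean())
        rows.append({
            "patient_id": pat, "region_id": reg,
            "n_binders": int(len(sample_binders)),
            "lost_allele_fraction": frac,
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", "n_binders", "lost_allele_fraction"
    ])
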