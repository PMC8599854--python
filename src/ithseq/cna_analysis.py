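"""Gene-level copy-number analysis: CNA calls, burden, Jaccard overlap,
oncogene-gain confirmation and LOH classification.

Segments are allele-specific copy-number intervals (1-based inclusive) with
a mean log2 tumor/normal ratio and integer major/minor allele counts. Calls
are made per gene: the length-weighted mean log2 of overlapping segments is
compared against strict +/-0.6 thresholds (exactly 0.6 is neutral). A CNA
*event* is a (gene, direction) pair throughout, which keeps burden counts
and Jaccard indices mutually consistent.

LOH classes come from the allele counts of the segment covering the gene
midpoint: (A=2, B=0) is copy-neutral LOH, (A=1, B=0) copy-loss LOH.

The packaged default gene model is a synthetic ~1000-gene panel constructed
in code (22 autosomes, real symbols for the genes the analyses care about:
TP53, RB1, the IFN-gamma pathway, an oncogene/TSG panel) so that no
annotation download is required; any BED-like gene table can be supplied
instead.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

GAIN_LOG2 = 0.6
LOSS_LOG2 = -0.6

IFNG_PATHWAY_GENES = (
    "IFNGR1", "IFNGR2", "JAK1", "JAK2", "STAT1", "IRF1", "B2M", "IFNG",
)

_NAMED_GENES = {
    # gene: (chrom, approx position rank within chrom 0..1)
    "TP53": ("chr17", 0.08), "RB1": ("chr13", 0.45), "PTEN": ("chr10", 0.85),
    "NOTCH1": ("chr9", 0.95), "CREBBP": ("chr16", 0.05), "EP300": ("chr22", 0.8),
    "MYC": ("chr8", 0.9), "MYCL": ("chr1", 0.25), "MYCN": ("chr2", 0.1),
    "KRAS": ("chr12", 0.2), "EGFR": ("chr7", 0.35), "PIK3CA": ("chr3", 0.9),
    "SOX2": ("chr3", 0.92), "FGFR1": ("chr8", 0.25), "KIT": ("chr4", 0.4),
    "BRAF": ("chr7", 0.9), "IFNG": ("chr12", 0.55), "IFNGR1": ("chr6", 0.85),
    "IFNGR2": ("chr21", 0.6), "JAK1": ("chr1", 0.45), "JAK2": ("chr9", 0.05),
    "STAT1": ("chr2", 0.75), "IRF1": ("chr5", 0.7), "B2M": ("chr15", 0.3),
    "HLA-A": ("chr6", 0.15), "HLA-B": ("chr6", 0.16), "HLA-C": ("chr6", 0.17),
}

_CHROM_SIZES = {f"chr{i}": 50_000_000 + 5_000_000 * ((23 - i)) for i in range(1, 23)}


def default_gene_model(n_genes: int = 1000) -> pd.DataFrame:
    """Synthetic gene model: ``n_genes`` non-overlapping genes on 22
    autosomes, deterministic, including the named panel genes above."""
    rows = []
    per_chrom = {c: 0 for c in _CHROM_SIZES}
    generic = n_genes - len(_NAMED_GENES)
    chroms = list(_CHROM_SIZES)
    for i in range(generic):
        per_chrom[chroms[i % len(chroms)]] += 1
    for gene, (chrom, frac) in _NAMED_GENES.items():
        size = _CHROM_SIZES[chrom]
        start = int(frac * size)
        rows.append({"gene": gene, "chrom": chrom, "start": start, "end": start + 20_000})
    for chrom, count in per_chrom.items():
        size = _CHROM_SIZES[chrom]
        # evenly spaced, offset to dodge the named genes
        for j in range(count):
            start = int((j + 0.5) / count * size) + 40_001
            rows.append(
                {"gene": f"G{chrom[3:]}_{j:03d}", "chrom": chrom, "start": start,
                 "end": start + 20_000}
            )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)
    # drop generic genes colliding with a neighbour so the model is disjoint
    named = set(_NAMED_GENES)
    keep, prev_end, prev_chrom = [], -1, None
    for _, g in df.iterrows():
        if g["chrom"] != prev_chrom:
            prev_end, prev_chrom = -1, g["chrom"]
        if g["start"] <= prev_end and g["gene"] not in named:
            continue
        if g["start"] <= prev_end and keep and keep[-1]["gene"] not in named:
            keep.pop()  # generic neighbour yields to the named gene
        keep.append(g)
        prev_end = g["end"]
    return pd.DataFrame(keep).reset_index(drop=True)


# ---------------------------------------------------------------------------

def _overlap(gs: int, ge: int, ss, se) -> np.ndarray:
    """Overlap lengths of a gene (gs, ge) with segment arrays (1-based incl.)."""
    return np.maximum(0, np.minimum(ge, se) - np.maximum(gs, ss) + 1)


def gene_level_cna(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-level CNA calls per (patient, region).

    mean_log2 is the overlap-length-weighted mean of the segments touching
    the gene; state is gain iff mean_log2 > 0.6, loss iff < -0.6, else
    neutral (strict inequalities). Genes with no overlapping segment are
    absent from the output. Also annotates the LOH class of the segment
    covering the gene midpoint (CNN_LOH for A=2/B=0, CNL_LOH for A=1/B=0).
    """
    out = []
    has_alleles = {"a_count", "b_count"} <= set(segments.columns)
    for (pat, reg), seg in segments.groupby(["patient_id", "region_id"]):
        for chrom, segc in seg.groupby("chrom"):
            gsub = genes[genes["chrom"] == chrom]
            if not len(gsub):
                continue
            ss, se = segc["start"].values, segc["end"].values
            for _, g in gsub.iterrows():
                ov = _overlap(g["start"], g["end"], ss, se)
                if ov.sum() == 0:
                    continue
                mean_log2 = float(np.average(segc["log2"].values, weights=ov))
                state = "gain" if mean_log2 > GAIN_LOG2 else (
                    "loss" if mean_log2 < LOSS_LOG2 else "neutral")
                loh = "none"
                if has_alleles:
                    mid = (g["start"] + g["end"]) // 2
                    cover = segc[(ss <= mid) & (se >= mid)]
                    if len(cover):
                        a, b = int(cover.iloc[0]["a_count"]), int(cover.iloc[0]["b_count"])
                        if (a, b) == (2, 0):
                            loh = "CNN_LOH"
                        elif (a, b) == (1, 0):
                            loh = "CNL_LOH"
                out.append({
                    "patient_id": pat, "region_id": reg, "gene": g["gene"],
                    "mean_log2": mean_log2, "state": state, "loh_class": loh,
                })
    return pd.DataFrame(
        out, columns=["patient_id", "region_id", "gene", "mean_log2", "state", "loh_class"]
    )


def cna_burden(calls: pd.DataFrame) -> pd.DataFrame:
    """CNA burden (count of non-neutral gene calls) per region and per tumor.

    The tumor row ('region_id' == 'tumor') counts the union of (gene,
    direction) events across the tumor's regions.
    """
    rows = []
    ev = calls[calls["state"] != "neutral"]
    for (pat, reg), grp in calls.groupby(["patient_id", "region_id"]):
        rows.append({
            "patient_id": pat, "region_id": reg,
            "cna_burden": int((grp["state"] != "neutral").sum()),
        })
    for pat, grp in ev.groupby("patient_id"):
        union = grp.drop_duplicates(subset=["gene", "state"])
        rows.append({"patient_id": pat, "region_id": "tumor", "cna_burden": len(union)})
    for pat in calls["patient_id"].unique():
        if not any(r["patient_id"] == pat and r["region_id"] == "tumor" for r in rows):
            rows.append({"patient_id": pat, "region_id": "tumor", "cna_burden": 0})
    return pd.DataFrame(rows).sort_values(["patient_id", "region_id"], ignore_index=True)


def cna_jaccard(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise region Jaccard over (gene, direction) CNA event sets.

    Returns (pairwise table, per-tumor mean table). Pairs where both
    regions are event-free get a missing JI.
    """
    pair_rows = []
    for pat, grp in calls.groupby("patient_id"):
        regions = sorted(grp["region_id"].unique())
        events = {
            r: set(map(tuple, grp[(grp["region_id"] == r) & (grp["state"] != "neutral")][
                ["gene", "state"]].values))
            for r in regions
        }
        for a, b in itertools.combinations(regions, 2):
            union = events[a] | events[b]
            ji = len(events[a] & events[b]) / len(union) if union else np.nan
            pair_rows.append({"patient_id": pat, "region_a": a, "region_b": b, "jaccard": ji})
    pairs = pd.DataFrame(pair_rows, columns=["patient_id", "region_a", "region_b", "jaccard"])
    means = (
        pairs.groupby("patient_id", as_index=False)["jaccard"].mean()
        if len(pairs)
        else pd.DataFrame(columns=["patient_id", "jaccard"])
    )
    return pairs, means


def oncogene_gain_filter(
    calls: pd.DataFrame,
    gene_cn: pd.DataFrame,
    ploidy: dict | pd.Series,
    oncogenes: set[str],
) -> pd.DataFrame:
    """Confirm oncogene gains against integer copy number and ploidy.

    An oncogene gain call survives iff its integer copy number (``gene_cn``
    columns patient_id, region_id, gene, cn) exceeds the region's overall
    ploidy. Non-oncogene calls pass through unmodified. Adds a
    ``confirmed`` column (True for everything except rejected oncogene
    gains).
    """
    cn_idx = gene_cn.set_index(["patient_id", "region_id", "gene"])["cn"]
    out = calls.copy()
    confirmed = []
    for _, row in out.iterrows():
        if row["gene"] in oncogenes and row["state"] == "gain":
            key = (row["patient_id"], row["region_id"], row["gene"])
            pl = ploidy[key[:2]] if isinstance(ploidy, (pd.Series, dict)) else ploidy
            cn = cn_idx.get(key, np.nan)
            confirmed.append(bool(cn > pl) if np.isfinite(cn) else False)
        else:
            confirmed.append(True)
    out["confirmed"] = confirmed
    return out


def classify_gene_loh(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """LOH class per (patient, region, gene) from allele counts.

    The class comes from the segment covering the gene midpoint (a
    deterministic tie-break for genes spanning several segments): CNN_LOH
    for (A=2, B=0), CNL_LOH for (A=1, B=0), none otherwise. Genes whose
    midpoint is uncovered are absent.
    """
    rows = []
    for (pat, reg), seg in segments.groupby(["patient_id", "region_id"]):
        for chrom, segc in seg.groupby("chrom"):
            gsub = genes[genes["chrom"] == chrom]
            ss, se = segc["start"].values, segc["end"].values
            for _, g in gsub.iterrows():
                mid = (g["start"] + g["end"]) // 2
                hit = np.flatnonzero((ss <= mid) & (se >= mid))
                if not len(hit):
                    continue
                a = int(segc.iloc[hit[0]]["a_count"])
                b = int(segc.iloc[hit[0]]["b_count"])
                loh = "CNN_LOH" if (a, b) == (2, 0) else (
                    "CNL_LOH" if (a, b) == (1, 0) else "none")
                rows.append({
                    "patient_id": pat, "region_id": reg, "gene": g["gene"],
                    "a_count": a, "b_count": b, "loh_class": loh,
                })
    return pd.DataFrame(
        rows, columns=["patient_id", "region_id", "gene", "a_count", "b_count", "loh_class"]
    )


def trunk_branch_loh(loh_calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trunk/branch status of LOH events and the per-tumor trunk fraction.

    An event is a (gene, loh_class != none) pair; it is trunk iff present
    in all of the tumor's regions with LOH data, branch otherwise. Returns
    (per-event table, per-tumor fraction table); single-region tumors are
    excluded.
    """
    ev_rows, frac_rows = [], []
    for pat, grp in loh_calls.groupby("patient_id"):
        regions = sorted(grp["region_id"].unique())
        if len(regions) < 2:
            continue
        events = grp[grp["loh_class"] != "none"]
        counts = events.groupby(["gene", "loh_class"])["region_id"].nunique()
        for (gene, cls), n in counts.items():
            ev_rows.append({
                "patient_id": pat, "gene": gene, "loh_class": cls,
                "n_regions": int(n), "status": "trunk" if n == len(regions) else "branch",
            })
        total = len(counts)
        trunk = int((counts == len(regions)).sum())
        frac_rows.append({
            "patient_id": pat, "n_events": total,
            "trunk_loh_fraction": trunk / total if total else np.nan,
        })
    return (
        pd.DataFrame(ev_rows, columns=["patient_id", "gene", "loh_class", "n_regions", "status"]),
        pd.DataFrame(frac_rows, columns=["patient_id", "n_events", "trunk_loh_fraction"]),
    )
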