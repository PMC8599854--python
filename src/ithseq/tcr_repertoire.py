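"""TCR-beta repertoire metrics and overlap statistics.

Per-sample metrics follow the immunoSEQ conventions: *density* is templates
per nucleated input cell, *richness* the count of unique productive
rearrangements, and *clonality* 1 minus Pielou's evenness,

    clonality = 1 - H / ln(R),   H = -sum p_i ln p_i,

computed on productive frequencies renormalised to sum to one (natural log;
defined as 0 for a single-clone repertoire). Overlap between two samples is
quantified three ways: the Jaccard index on rearrangement sets, the
Morisita-Horn index on template counts (abundance-weighted, scale
invariant) and the shared fraction of the top-20 most frequent clonotypes.
Nucleotide rearrangement identity is the clonotype unit throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RepertoireMetrics:
    sample: str
    density: float  # templates per nucleated cell; NaN if input_cells unusable
    richness: int
    clonality: float
    total_templates: int


def repertoire_metrics(table) -> RepertoireMetrics:
    """Density, richness and clonality for one clonotype table.

    ``table`` is a ClonotypeTable (io_cohort) or any object with ``rows``
    (DataFrame with rearrangement/templates/productive_frequency),
    ``total_templates``, ``input_cells`` and a ``sample`` label.
    """
    rows = table.rows
    if len(rows) == 0:
        raise ValueError("repertoire has no rearrangements")
    richness = rows["rearrangement"].nunique()
    p = rows["productive_frequency"].to_numpy(dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    if richness <= 1:
        clonality = 0.0
    else:
        H = float(-(p * np.log(p)).sum())
        clonality = float(np.clip(1.0 - H / np.log(richness), 0.0, 1.0))
    density = (
        table.total_templates / table.input_cells
        if table.input_cells and table.input_cells > 0
        else float("nan")
    )
    return RepertoireMetrics(
        sample=table.sample,
        density=float(density),
        richness=int(richness),
        clonality=clonality,
        total_templates=int(table.total_templates),
    )


@dataclass
class OverlapMetrics:
    sample_a: str
    sample_b: str
    jaccard: float
    morisita: float
    top20_shared: float


def _top_n(rows: pd.DataFrame, n: int = 20) -> set[str]:
    # highest frequency first; ties broken by rearrangement string order
    ranked = rows.sort_values(
        ["productive_frequency", "rearrangement"], ascending=[False, True]
    )
    return set(ranked["rearrangement"].head(n))


def overlap_metrics(a, b, top_n: int = 20) -> OverlapMetrics:
    """Jaccard, Morisita-Horn and top-20 sharing between two repertoires."""
    ra, rb = a.rows, b.rows
    sa, sb = set(ra["rearrangement"]), set(rb["rearrangement"])
    union = sa | sb
    jaccard = len(sa & sb) / len(union) if union else float("nan")

    xa = ra.set_index("rearrangement")["templates"].astype(float)
    xb = rb.set_index("rearrangement")["templates"].astype(float)
    X, Y = xa.sum(), xb.sum()
    common = xa.index.intersection(xb.index)
    num = 2.0 * float((xa.loc[common] * xb.loc[common]).sum())
    den = (float((xa**2).sum()) / X**2 + float((xb**2).sum()) / Y**2) * X * Y
    morisita = num / den if den > 0 else float("nan")

    n = min(top_n, len(sa), len(sb), top_n)
    ta, tb = _top_n(ra, top_n), _top_n(rb, top_n)
    denom = min(top_n, max(len(ta), len(tb)))
    top_shared = len(ta & tb) / denom if denom else float("nan")
    return OverlapMetrics(a.sample, b.sample, float(jaccard), float(morisita), float(top_shared))


def sharing_classes(tables: list) -> dict[str, float]:
    """Proportions of clonotypes seen in all / some / one region of a tumor.

    Over the union of rearrangements across the given region tables,
    returns the fractions present in every region ('shared'), in at least
    two but not all ('intermediate'), and in exactly one ('private'); they
    sum to 1. Undefined (error) for fewer than two regions.
    """
    if len(tables) < 2:
        raise ValueError("sharing classes need at least two regions")
    sets = [set(t.rows["rearrangement"]) for t in tables]
    union = set().union(*sets)
    if not union:
        raise ValueError("empty repertoires")
    n = len(sets)
    counts = {r: sum(r in s for s in sets) for r in union}
    total = len(union)
    shared = sum(1 for c in counts.values() if c == n) / total
    private = sum(1 for c in counts.values() if c == 1) / total
    intermediate = 1.0 - shared - private
    return {"shared": shared, "intermediate": max(intermediate, 0.0), "private": private}


def tumor_vs_adjacent_contrast(
    tumor: pd.DataFrame, adjacent: pd.DataFrame, metrics=("density", "richness", "clonality")
) -> pd.DataFrame:
    """Compare tumor vs adjacent-lung repertoire metrics.

    Both frames need a patient_id column plus the metric columns. Patients
    with both a tumor and an adjacent sample are compared with a two-sided
    Wilcoxon signed-rank test on patient-matched pairs (tumor values
    averaged over regions); if fewer than 3 matched pairs exist, an
    unpaired two-sided Mann-Whitney test over all samples is used instead
    (the ``test`` column records which). Errors when fewer than 3 total
    contrasts are possible.
    """
    t_by_pat = tumor.groupby("patient_id")[list(metrics)].mean()
    a_by_pat = adjacent.groupby("patient_id")[list(metrics)].mean()
    matched = t_by_pat.index.intersection(a_by_pat.index)
    rows = []
    for m in metrics:
        if len(matched) >= 3:
            x = t_by_pat.loc[matched, m].to_numpy()
            y = a_by_pat.loc[matched, m].to_numpy()
            if np.allclose(x, y):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(x, y)
                stat, p = float(res.statistic), float(res.pvalue)
            test = "wilcoxon_paired"
        else:
            if min(len(tumor), len(adjacent)) < 3:
                raise ValueError("need at least 3 pairs or 3 samples per group")
            res = stats.mannwhitneyu(tumor[m], adjacent[m], alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            test = "mannwhitney"
        rows.append({"metric": m, "test": test, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def pairwise_overlap_table(tables: list) -> pd.DataFrame:
    """All pairwise overlap metrics among a list of clonotype tables."""
    rows = []
    for a, b in itertools.combinations(tables, 2):
        om = overlap_metrics(a, b)
        rows.append(vars(om))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "jaccard", "morisita", "top20_shared"]
    )
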