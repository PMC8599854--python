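"""Somatic variant QC for multi-region FFPE exomes.

Implements the study-grade filter stack for MuTect-style calls: coverage,
VAF, alt-read support, population-frequency and log-odds (LOD) thresholds,
plus two FFPE-specific devices:

* an elevated LOD threshold (default 18 at region level, 30 at tumor level
  vs the caller default of 6.3) that suppresses formalin artifacts, which
  present as low-LOD, low-VAF C>T|G>A transitions; and
* a *rescue* rule — a call failing only the LOD rule is kept if the
  identical mutation (same chrom, pos, ref, alt) passed in another region
  of the same tumor. Tumor-level calls are analogously rescued from the
  region-level pass set.

Substitution-spectrum summaries stratified by LOD provide the QC readout:
an FFPE-contaminated stratum shows an excess of C>T|G>A, while genuine
smoking-related mutations are dominated by C>A|G>T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NONSILENT_CLASSES = frozenset({"nonsynonymous", "frameshift", "stopgain", "stoploss"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class FilterThresholds:
    """Region/tumor-level somatic filter thresholds.

    Depth and alt-read rules are inclusive (>=); VAF-in-tumor inclusive;
    normal VAF and population frequencies strict (<); the LOD rule is
    strictly greater-than.
    """

    min_t_depth: int = 20
    min_n_depth: int = 10
    min_t_vaf: float = 0.02
    max_n_vaf: float = 0.01
    min_alt_reads: int = 4
    max_popfreq: float = 0.01
    lod_region: float = 18.0
    lod_tumor: float = 30.0

    def __post_init__(self):
        if self.lod_tumor < self.lod_region:
            raise ValueError("lod_tumor must be >= lod_region")


def _fail_reasons(df: pd.DataFrame, thr: FilterThresholds, lod: float) -> pd.Series:
    pop = [c for c in ("popfreq_esp", "popfreq_1kg", "popfreq_exac") if c in df.columns]
    checks = {
        "min_t_depth": df["t_depth"] >= thr.min_t_depth,
        "min_n_depth": df["n_depth"] >= thr.min_n_depth,
        "min_t_vaf": df["t_vaf"] >= thr.min_t_vaf,
        "max_n_vaf": df["n_vaf"] < thr.max_n_vaf,
        "min_alt_reads": df["t_alt"] >= thr.min_alt_reads,
        "max_popfreq": pd.concat(
            [df[c].fillna(0.0) < thr.max_popfreq for c in pop], axis=1
        ).all(axis=1)
        if pop
        else pd.Series(True, index=df.index),
        "lod": df["lod"] > lod,
    }
    ok = pd.DataFrame(checks)
    return ok.apply(lambda row: tuple(name for name, v in row.items() if not v), axis=1)


def apply_region_filters(
    variants: pd.DataFrame, thr: FilterThresholds | None = None, level: str = "region"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split calls into (pass, fail-with-reasons) at region or tumor level.

    ``level`` selects the LOD threshold ('region' -> lod_region, 'tumor' ->
    lod_tumor); all other rules are shared. Missing population frequencies
    are treated as 0. The fail frame gains a ``fail_reasons`` tuple column.
    """
    thr = thr or FilterThresholds()
    if level not in ("region", "tumor"):
        raise ValueError("level must be 'region' or 'tumor'")
    lod = thr.lod_region if level == "region" else thr.lod_tumor
    if len(variants) == 0:
        empty = variants.copy()
        fail = variants.copy()
        fail["fail_reasons"] = pd.Series(dtype=object)
        return empty, fail
    reasons = _fail_reasons(variants, thr, lod)
    passed = variants[reasons.map(len) == 0].copy()
    failed = variants[reasons.map(len) > 0].copy()
    failed["fail_reasons"] = reasons[reasons.map(len) > 0]
    return passed, failed


_KEY = ["patient_id", "chrom", "pos", "ref", "alt"]


def rescue_by_region(
    passed: pd.DataFrame,
    failed: pd.DataFrame,
    reference_pass: pd.DataFrame | None = None,
    lod_min: float = 18.0,
) -> pd.DataFrame:
    """Rescue calls whose only violated rule is the LOD rule.

    A failing call is rescued iff the identical mutation (patient, chrom,
    pos, ref, alt) is present in the reference pass set — by default the
    region-level pass set itself, restricted to *other* regions of the same
    tumor — with LOD >= ``lod_min``. For tumor-level rescue pass the
    region-level pass set as ``reference_pass`` (region disjointness is then
    not required). Rescued rows are returned with ``rescued=True``.
    """
    if len(failed) == 0:
        return failed.assign(rescued=pd.Series(dtype=bool))
    lod_only = failed["fail_reasons"].map(lambda r: r == ("lod",))
    candidates = failed[lod_only]
    ref = passed if reference_pass is None else reference_pass
    ref = ref[ref["lod"] >= lod_min]
    same_region_matters = reference_pass is None
    rescued_rows = []
    ref_keys = ref.set_index(_KEY)
    for _, row in candidates.iterrows():
        key = tuple(row[k] for k in _KEY)
        try:
            hits = ref_keys.loc[[key]]
        except KeyError:
            continue
        if same_region_matters:
            hits = hits[hits["region_id"] != row["region_id"]]
        if len(hits):
            rescued_rows.append(row)
    if not rescued_rows:
        out = failed.iloc[0:0].copy()
        out["rescued"] = pd.Series(dtype=bool)
        return out
    out = pd.DataFrame(rescued_rows)
    out["rescued"] = True
    return out.drop(columns=["fail_reasons"])


def filter_and_rescue(
    variants: pd.DataFrame, thr: FilterThresholds | None = None
) -> pd.DataFrame:
    """Region-level filters plus LOD rescue; returns the retained calls
    with a ``rescued`` flag."""
    passed, failed = apply_region_filters(variants, thr, level="region")
    rescued = rescue_by_region(passed, failed)
    passed = passed.copy()
    passed["rescued"] = False
    return pd.concat([passed, rescued], ignore_index=True)


# ---------------------------------------------------------------------------
# substitution spectrum QC

def _collapse_substitution(ref: str, alt: str) -> str | None:
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref in "AG":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    sub = f"{ref}>{alt}"
    return sub if sub in SPECTRUM_CLASSES else None


def substitution_spectrum(
    variants: pd.DataFrame, lod_cut: float = 18.0
) -> pd.DataFrame:
    """Pyrimidine-collapsed substitution-class proportions per LOD stratum.

    SNVs only; strata are 'low' (lod <= cut) and 'high' (lod > cut). Strata
    without SNVs are omitted. Proportions sum to 1 within each stratum.
    """
    subs = variants.apply(
        lambda r: _collapse_substitution(str(r["ref"]), str(r["alt"])), axis=1
    ) if len(variants) else pd.Series(dtype=object)
    snv = variants[subs.notna()].copy() if len(variants) else variants.copy()
    if len(snv) == 0:
        return pd.DataFrame(columns=["stratum", *SPECTRUM_CLASSES])
    snv["sub"] = subs[subs.notna()]
    snv["stratum"] = np.where(snv["lod"] > lod_cut, "high", "low")
    rows = []
    for stratum, grp in snv.groupby("stratum"):
        props = grp["sub"].value_counts(normalize=True)
        rows.append({"stratum": stratum, **{c: float(props.get(c, 0.0)) for c in SPECTRUM_CLASSES}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cancer-gene classification and TMB

DEFAULT_GENE_ROLES = {
    "TP53": "TSG", "RB1": "TSG", "PTEN": "TSG", "NOTCH1": "TSG", "CREBBP": "TSG",
    "EP300": "TSG", "ARID1A": "TSG", "SMARCA4": "TSG", "STK11": "TSG", "B2M": "TSG",
    "KRAS": "oncogene", "EGFR": "oncogene", "MYC": "oncogene", "MYCL": "oncogene",
    "MYCN": "oncogene", "PIK3CA": "oncogene", "SOX2": "oncogene", "FGFR1": "oncogene",
    "KIT": "oncogene", "BRAF": "oncogene",
}

DEFAULT_HOTSPOTS: frozenset[tuple[str, int, str, str]] = frozenset()


def classify_cancer_gene_alterations(
    variants: pd.DataFrame,
    gene_roles: dict[str, str] | None = None,
    hotspots: set | frozenset | None = None,
) -> pd.DataFrame:
    """Flag cancer-gene alterations.

    A variant qualifies iff it matches a known oncogene hotspot (gene, pos,
    ref, alt), or is a stopgain/frameshift in a tumor-suppressor gene, or is
    nonsynonymous with CADD > 20 (missing CADD is conservatively not >20).
    """
    roles = DEFAULT_GENE_ROLES if gene_roles is None else gene_roles
    hs = DEFAULT_HOTSPOTS if hotspots is None else hotspots
    out = variants.copy()
    is_hot = out.apply(
        lambda r: (str(r["gene"]), int(r["pos"]), str(r["ref"]), str(r["alt"])) in hs, axis=1
    ) if len(out) else pd.Series(dtype=bool)
    is_tsg_trunc = out["gene"].map(lambda g: roles.get(g) == "TSG") & out[
        "func_class"
    ].isin(["stopgain", "frameshift"])
    cadd = pd.to_numeric(out["cadd"], errors="coerce")
    is_cadd = (out["func_class"] == "nonsynonymous") & (cadd > 20)
    out["cancer_gene_alteration"] = (
        is_hot.astype(bool) | is_tsg_trunc.astype(bool) | is_cadd.astype(bool)
    )
    return out


def compute_tmb(variants: pd.DataFrame, capture_mb: float = 30.0) -> pd.DataFrame:
    """Nonsilent mutations per megabase, per region and per tumor.

    The tumor value counts the union of distinct nonsilent loci across
    regions. ``capture_mb`` is the exome footprint used for normalisation.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    ns = variants[variants["func_class"].isin(NONSILENT_CLASSES)]
    rows = []
    for (pat, reg), grp in ns.groupby(["patient_id", "region_id"]):
        rows.append({"patient_id": pat, "region_id": reg, "tmb": len(grp) / capture_mb})
    # regions with zero nonsilent calls still get a row
    for (pat, reg), _ in variants.groupby(["patient_id", "region_id"]):
        if not any(r["patient_id"] == pat and r["region_id"] == reg for r in rows):
            rows.append({"patient_id": pat, "region_id": reg, "tmb": 0.0})
    for pat, grp in ns.groupby("patient_id"):
        n = grp.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).shape[0]
        rows.append({"patient_id": pat, "region_id": "tumor", "tmb": n / capture_mb})
    for pat, _ in variants.groupby("patient_id"):
        if not any(r["patient_id"] == pat and r["region_id"] == "tumor" for r in rows):
            rows.append({"patient_id": pat, "region_id": "tumor", "tmb": 0.0})
    return pd.DataFrame(rows, columns=["patient_id", "region_id", "tmb"]).sort_values(
        ["patient_id", "region_id"], ignore_index=True
    )
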