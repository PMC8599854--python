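"""Data model, file dialects and validation for multi-region tumor cohorts.

One *bundle* holds everything known about a patient's tumor: per-region
somatic variant calls (MAF-like), allele-specific copy-number segments
(SEG-like, plus integer major/minor allele counts), per-region purity and
ploidy, class-I HLA genotype and binned allele-specific copy estimates,
predicted neoantigens, TCR-beta clonotype tables and the clinical record.

Dialects (all delimited text, UTF-8, "." for missing, 1-based inclusive
coordinates following MAF/SEG conventions):

* variants.tsv     — fixed column order, one row per (region, mutation)
* segments.tsv     — patient, region, chrom, start, end, log2, a_count, b_count
* samples.tsv      — per-region purity and ploidy
* clinical.csv     — one row per patient (comma-separated)
* neoantigens.tsv  — mutation key, peptide, presenting allele, ic50_nm
* hla_genotypes.tsv / hla_allele_cn.tsv — class-I alleles and binned copies
* clonotypes/<patient>_<region>.tsv — immunoSEQ-style, with a two-line
  ``#total_templates=`` / ``#input_cells=`` header

``adjacent_lung`` is a reserved region id for non-tumor repertoires.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ADJACENT_LUNG = "adjacent_lung"

VARIANT_COLUMNS = [
    "patient_id", "region_id", "chrom", "pos", "ref", "alt", "gene", "func_class",
    "t_depth", "n_depth", "t_alt", "t_vaf", "n_vaf", "lod", "cadd",
    "popfreq_esp", "popfreq_1kg", "popfreq_exac", "tnc",
]
SEGMENT_COLUMNS = [
    "patient_id", "region_id", "chrom", "start", "end", "log2", "a_count", "b_count",
]
SAMPLE_COLUMNS = ["patient_id", "region_id", "purity", "ploidy"]
CLINICAL_COLUMNS = [
    "patient_id", "os_months", "os_event", "stage", "age", "sex", "smoking",
    "tumor_size_cm",
]
NEOANTIGEN_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "peptide", "allele", "ic50_nm",
]
FUNC_CLASSES = {"nonsynonymous", "frameshift", "stopgain", "stoploss", "synonymous", "other"}

MISSING = "."


class CohortFormatError(ValueError):
    """Malformed input naming file, line and column where known."""


@dataclass
class ClonotypeTable:
    """One sample's TCR-beta repertoire."""

    patient_id: str
    region_id: str
    rows: pd.DataFrame  # rearrangement, templates, productive_frequency
    total_templates: int
    input_cells: int

    @property
    def sample(self) -> str:
        return f"{self.patient_id}:{self.region_id}"


@dataclass
class TumorBundle:
    """All observations for one patient."""

    patient_id: str
    regions: list[str]
    variants: pd.DataFrame
    segments: pd.DataFrame
    purity: dict[str, float] = field(default_factory=dict)
    ploidy: dict[str, float] = field(default_factory=dict)
    hla_genotype: list[str] = field(default_factory=list)
    hla_allele_cn: pd.DataFrame = field(default_factory=pd.DataFrame)
    neoantigens: pd.DataFrame = field(default_factory=pd.DataFrame)
    clinical: dict = field(default_factory=dict)
    repertoires: dict[str, ClonotypeTable] = field(default_factory=dict)


@dataclass
class Cohort:
    bundles: dict[str, TumorBundle]

    @property
    def patients(self) -> list[str]:
        return sorted(self.bundles)

    @property
    def variants(self) -> pd.DataFrame:
        frames = [b.variants for b in self.bundles.values() if len(b.variants)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=VARIANT_COLUMNS)

    @property
    def segments(self) -> pd.DataFrame:
        frames = [b.segments for b in self.bundles.values() if len(b.segments)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEGMENT_COLUMNS)

    @property
    def clinical(self) -> pd.DataFrame:
        rows = [b.clinical for b in self.bundles.values() if b.clinical]
        return pd.DataFrame(rows) if rows else pd.DataFrame(columns=CLINICAL_COLUMNS)


# ---------------------------------------------------------------------------
# readers

def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")


def read_variants(path) -> pd.DataFrame:
    """Read and row-validate the MAF-like variant table (1-based positions)."""
    df = pd.read_csv(path, sep="\t", na_values=MISSING, keep_default_na=False,
                     dtype={"chrom": str, "patient_id": str, "region_id": str})
    _require_columns(df, VARIANT_COLUMNS, path)
    df = df[VARIANT_COLUMNS]
    # line numbers: header is line 1
    for i, row in df.iterrows():
        line = i + 2
        if not row["pos"] >= 1:
            raise CohortFormatError(f"{path}, line {line}, column pos: must be >= 1")
        if not 0 <= row["t_vaf"] <= 1:
            raise CohortFormatError(f"{path}, line {line}, column t_vaf: must be in [0, 1]")
        if row["t_alt"] > row["t_depth"]:
            raise CohortFormatError(
                f"{path}, line {line}, column t_alt: exceeds t_depth"
            )
        if pd.notna(row["func_class"]) and row["func_class"] not in FUNC_CLASSES:
            raise CohortFormatError(
                f"{path}, line {line}, column func_class: unknown class {row['func_class']!r}"
            )
    key = df[["patient_id", "region_id", "chrom", "pos", "ref", "alt"]]
    dup = key.duplicated()
    if dup.any():
        first = key[dup].iloc[0].tolist()
        raise CohortFormatError(f"{path}: duplicate variant key {tuple(first)}")
    return df


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=MISSING, keep_default_na=False,
                     dtype={"chrom": str, "patient_id": str, "region_id": str})
    _require_columns(df, SEGMENT_COLUMNS, path)
    df = df[SEGMENT_COLUMNS]
    for i, row in df.iterrows():
        line = i + 2
        if row["start"] > row["end"]:
            raise CohortFormatError(f"{path}, line {line}, column start: start > end")
        if not row["a_count"] >= row["b_count"] >= 0:
            raise CohortFormatError(
                f"{path}, line {line}, column a_count: need a_count >= b_count >= 0"
            )
    return df


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=MISSING, keep_default_na=False,
                     dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, path)
    return df[CLINICAL_COLUMNS]


def read_clonotype_table(path) -> ClonotypeTable:
    """Read one immunoSEQ-style clonotype TSV with its two-line meta header."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for _ in range(2):
            line = fh.readline().strip()
            if not line.startswith("#") or "=" not in line:
                raise CohortFormatError(f"{path}: expected '#key=value' header line")
            k, v = line[1:].split("=", 1)
            meta[k] = int(v)
        rows = pd.read_csv(fh, sep="\t")
    _require_columns(rows, ["rearrangement", "templates", "productive_frequency"], path)
    if (rows["templates"] < 1).any():
        raise CohortFormatError(f"{path}: templates must be >= 1")
    stem = path.stem
    patient, _, region = stem.partition("_")
    return ClonotypeTable(
        patient_id=patient, region_id=region, rows=rows,
        total_templates=meta.get("total_templates", int(rows["templates"].sum())),
        input_cells=meta.get("input_cells", 0),
    )


def load_cohort(
    variant_path,
    segment_path,
    clonotype_dir=None,
    clinical_path=None,
    config: dict | None = None,
) -> Cohort:
    """Assemble a validated cohort from the on-disk dialects.

    ``config`` may carry paths for the optional tables: ``samples``
    (purity/ploidy), ``neoantigens``, ``hla_genotypes``, ``hla_allele_cn``.
    Missing optional tables yield empty collections.
    """
    config = config or {}
    variants = read_variants(variant_path)
    segments = read_segments(segment_path)
    clinical = read_clinical(clinical_path) if clinical_path else pd.DataFrame(columns=CLINICAL_COLUMNS)

    samples = (
        pd.read_csv(config["samples"], sep="\t", dtype={"patient_id": str, "region_id": str})
        if config.get("samples") else pd.DataFrame(columns=SAMPLE_COLUMNS)
    )
    neo = (
        pd.read_csv(config["neoantigens"], sep="\t", na_values=MISSING,
                    dtype={"chrom": str, "patient_id": str})
        if config.get("neoantigens") else pd.DataFrame(columns=NEOANTIGEN_COLUMNS)
    )
    hla = (
        pd.read_csv(config["hla_genotypes"], sep="\t", dtype=str)
        if config.get("hla_genotypes") else pd.DataFrame(columns=["patient_id", "gene", "allele"])
    )
    hla_cn = (
        pd.read_csv(config["hla_allele_cn"], sep="\t", dtype={"patient_id": str, "region_id": str})
        if config.get("hla_allele_cn") else pd.DataFrame(
            columns=["patient_id", "region_id", "gene", "allele", "bin", "cn"])
    )
    repertoires: dict[str, list[ClonotypeTable]] = {}
    if clonotype_dir:
        for p in sorted(Path(clonotype_dir).glob("*.tsv")):
            t = read_clonotype_table(p)
            repertoires.setdefault(t.patient_id, []).append(t)

    patients = sorted(
        set(variants["patient_id"]) | set(segments["patient_id"]) | set(clinical["patient_id"])
    )
    bundles = {}
    for pat in patients:
        v = variants[variants["patient_id"] == pat].reset_index(drop=True)
        s = segments[segments["patient_id"] == pat].reset_index(drop=True)
        samp = samples[samples["patient_id"] == pat]
        regions = sorted(
            set(v["region_id"]) | set(s["region_id"]) | set(samp["region_id"])
        )
        clin_rows = clinical[clinical["patient_id"] == pat]
        bundles[pat] = TumorBundle(
            patient_id=pat,
            regions=regions,
            variants=v,
            segments=s,
            purity=dict(zip(samp["region_id"], samp["purity"])),
            ploidy=dict(zip(samp["region_id"], samp["ploidy"])),
            hla_genotype=sorted(hla[hla["patient_id"] == pat]["allele"]),
            hla_allele_cn=hla_cn[hla_cn["patient_id"] == pat].reset_index(drop=True),
            neoantigens=neo[neo["patient_id"] == pat].reset_index(drop=True),
            clinical=clin_rows.iloc[0].to_dict() if len(clin_rows) else {},
            repertoires={t.region_id: t for t in repertoires.get(pat, [])},
        )
    return Cohort(bundles)


# ---------------------------------------------------------------------------
# validation report

def validate_cohort(cohort: Cohort, freq_tol: float = 1e-6) -> list[dict]:
    """Check every type invariant; returns violations (empty iff clean).

    Each entry carries patient, table and rule; violations are data, not
    exceptions.
    """
    report = []

    def add(patient, table, rule, detail=""):
        report.append({"patient": patient, "table": table, "rule": rule, "detail": detail})

    for pat, b in cohort.bundles.items():
        v = b.variants
        if len(v):
            if (v["pos"] < 1).any():
                add(pat, "variants", "pos_ge_1")
            if ((v["t_vaf"] < 0) | (v["t_vaf"] > 1)).any():
                add(pat, "variants", "t_vaf_in_unit_interval")
            if (v["t_alt"] > v["t_depth"]).any():
                add(pat, "variants", "t_alt_le_t_depth")
            dup = v.duplicated(subset=["region_id", "chrom", "pos", "ref", "alt"])
            if dup.any():
                add(pat, "variants", "unique_variant_key", f"{int(dup.sum())} duplicates")
            bad_regions = set(v["region_id"]) - set(b.regions)
            if bad_regions:
                add(pat, "variants", "region_known", str(sorted(bad_regions)))
        s = b.segments
        if len(s):
            if (s["start"] > s["end"]).any():
                add(pat, "segments", "start_le_end")
            if ((s["a_count"] < s["b_count"]) | (s["b_count"] < 0)).any():
                add(pat, "segments", "allele_counts_ordered")
            for (reg, chrom), grp in s.groupby(["region_id", "chrom"]):
                g = grp.sort_values("start")
                prev_end, prev_row = None, None
                for idx, row in g.iterrows():
                    if prev_end is not None and row["start"] <= prev_end:
                        add(pat, "segments", "non_overlapping",
                            f"{reg} {chrom}: rows {prev_row} and {idx}")
                    prev_end, prev_row = row["end"], idx
        for reg, t in b.repertoires.items():
            tot = t.rows["productive_frequency"].sum()
            if tot > 1 + max(freq_tol, 1e-3):
                add(pat, f"repertoire:{reg}", "productive_freq_le_1", f"sum={tot:.4f}")
            if (t.rows["templates"] < 1).any():
                add(pat, f"repertoire:{reg}", "templates_ge_1")
            if t.rows["rearrangement"].duplicated().any():
                add(pat, f"repertoire:{reg}", "unique_rearrangements")
            if reg != ADJACENT_LUNG and reg not in b.regions:
                add(pat, f"repertoire:{reg}", "region_known")
        if len(b.neoantigens) and len(v):
            vkeys = set(zip(v["chrom"].astype(str), v["pos"].astype(int),
                            v["ref"], v["alt"]))
            nk = set(zip(b.neoantigens["chrom"].astype(str), b.neoantigens["pos"].astype(int),
                         b.neoantigens["ref"], b.neoantigens["alt"]))
            orphan = nk - vkeys
            if orphan:
                add(pat, "neoantigens", "locus_matches_variant", f"{len(orphan)} orphan loci")
    return report


# ---------------------------------------------------------------------------
# writers

def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a cohort back to the on-disk dialects (inverse of load_cohort)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    _df_to_tsv(cohort.variants, out / "variants.tsv")
    _df_to_tsv(cohort.segments, out / "segments.tsv")
    cohort.clinical.to_csv(out / "clinical.csv", index=False, na_rep=MISSING)
    samples = pd.DataFrame([
        {"patient_id": p, "region_id": r, "purity": b.purity.get(r), "ploidy": b.ploidy.get(r)}
        for p, b in sorted(cohort.bundles.items()) for r in b.regions
    ], columns=SAMPLE_COLUMNS)
    _df_to_tsv(samples, out / "samples.tsv")
    neo = [b.neoantigens for b in cohort.bundles.values() if len(b.neoantigens)]
    _df_to_tsv(pd.concat(neo, ignore_index=True) if neo else
               pd.DataFrame(columns=NEOANTIGEN_COLUMNS), out / "neoantigens.tsv")
    hla = pd.DataFrame([
        {"patient_id": p, "gene": a.split("*")[0], "allele": a}
        for p, b in sorted(cohort.bundles.items()) for a in b.hla_genotype
    ], columns=["patient_id", "gene", "allele"])
    _df_to_tsv(hla, out / "hla_genotypes.tsv")
    cn = [b.hla_allele_cn for b in cohort.bundles.values() if len(b.hla_allele_cn)]
    _df_to_tsv(pd.concat(cn, ignore_index=True) if cn else
               pd.DataFrame(columns=["patient_id", "region_id", "gene", "allele", "bin", "cn"]),
               out / "hla_allele_cn.tsv")
    clono = out / "clonotypes"
    clono.mkdir(exist_ok=True)
    for p, b in sorted(cohort.bundles.items()):
        for reg, t in sorted(b.repertoires.items()):
            fp = clono / f"{p}_{reg}.tsv"
            with open(fp, "w") as fh:
                fh.write(f"#total_templates={t.total_templates}\n")
                fh.write(f"#input_cells={t.input_cells}\n")
                t.rows.to_csv(fh, sep="\t", index=False, na_rep=MISSING, float_format="%.8g")
    for name in ("variants.tsv", "segments.tsv", "clinical.csv", "samples.tsv",
                 "neoantigens.tsv", "hla_genotypes.tsv", "hla_allele_cn.tsv"):
        paths[name] = out / name
    paths["clonotypes"] = clono
    return paths


def cohort_paths(out_dir) -> dict:
    """The load_cohort arguments for a directory written by write_cohort."""
    out = Path(out_dir)
    return {
        "variant_path": out / "variants.tsv",
        "segment_path": out / "segments.tsv",
        "clonotype_dir": out / "clonotypes",
        "clinical_path": out / "clinical.csv",
        "config": {
            "samples": out / "samples.tsv",
            "neoantigens": out / "neoantigens.tsv",
            "hla_genotypes": out / "hla_genotypes.tsv",
            "hla_allele_cn": out / "hla_allele_cn.tsv",
        },
    }


def config_hash(config) -> str:
    """Stable short hash of a (JSON-serialisable) configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(results: dict[str, pd.DataFrame], out_dir, config=None) -> pd.DataFrame:
    """Write named result tables as TSVs plus a manifest.

    The manifest lists file name, row count and the config hash; output is
    byte-identical across runs on identical inputs. A file-name collision
    between sanitised table names is an error raised before anything is
    written.
    """
    out = Path(out_dir)
    names = {}
    for name in results:
        fname = name.replace(" ", "_").replace("/", "_") + ".tsv"
        if fname in names:
            raise ValueError(f"result table name collision: {name!r} vs {names[fname]!r}")
        names[fname] = name
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config or {})
    rows = []
    for fname, name in sorted(names.items()):
        df = results[name]
        _df_to_tsv(df, out / fname)
        rows.append({"table": name, "file": fname, "n_rows": int(len(df)), "config_hash": chash})
    manifest = pd.DataFrame(rows, columns=["table", "file", "n_rows", "config_hash"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
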