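"""Readers and writers for the cohort directory formats.

Formats: SEG (tab-separated: sample, chromosome, start, end, num_mark,
seg_mean; 1-based inclusive), TSV matrices (features in rows, header row of
sample ids), minimal MAF (Hugo_Symbol, Tumor_Sample_Barcode,
Variant_Classification), clinical TSV (sample, os_time, os_event).
Writers mirror readers bit-exactly so round-trips are byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import OmicsMatrix, validate_annotation, validate_survival
from .synthetic import SyntheticCohort

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "num_mark", "seg_mean"]

COHORT_FILES = {
    "cnv.seg": "segmented copy number",
    "met_beta.tsv": "methylation beta matrix (probes x samples)",
    "expr_counts.tsv": "expression counts (genes x samples)",
    "expr_log.tsv": "log2 expression (genes x samples)",
    "mutations.maf": "minimal MAF",
    "clinical.tsv": "survival table",
    "annotation.tsv": "probe annotation",
    "genes.tsv": "gene model",
    "truth.tsv": "true subtype per sample",
}

_FLOAT_FMT = "%.10g"


def read_seg(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS[:4] + ["seg_mean"] if c not in seg.columns]
    if missing:
        raise ValueError(f"{path}: SEG missing columns {missing}")
    bad = seg.index[seg["start"] > seg["end"]]
    if len(bad):
        raise ValueError(f"{path}: start > end at line {bad[0] + 2}")
    if (seg["start"] < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    seg["chromosome"] = seg["chromosome"].astype(str)
    return seg


def write_seg(seg: pd.DataFrame, path) -> None:
    cols = [c for c in SEG_COLUMNS if c in seg.columns]
    seg[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_matrix(path, assay: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()][:3]
        raise ValueError(f"{path}: duplicated feature ids {list(dupes)}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicated sample ids")
    return OmicsMatrix(df, assay)


def write_matrix(m: OmicsMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_maf(path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep="\t")
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if col not in maf.columns:
            raise ValueError(f"{path}: MAF missing column {col!r}")
    return maf


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    if clin["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return validate_survival(clin)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", keep_default_na=False,
                      dtype={"gene": str, "chromosome": str})
    return validate_annotation(ann)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort directory (see COHORT_FILES); deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_seg(cohort.segments, outdir / "cnv.seg")
    write_matrix(cohort.met, outdir / "met_beta.tsv")
    write_matrix(cohort.expr_counts, outdir / "expr_counts.tsv")
    write_matrix(cohort.expr_log, outdir / "expr_log.tsv")
    cohort.mutations.to_csv(outdir / "mutations.maf", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    cohort.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    cohort.gene_model.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cohort.truth.labels.rename("subtype").to_frame().to_csv(
        outdir / "truth.tsv", sep="\t")
    pd.DataFrame({
        "gene": sorted(set(cohort.truth.cnvcor_genes)
                       | set(cohort.truth.metcor_genes)),
    }).assign(
        cnvcor=lambda d: d["gene"].isin(cohort.truth.cnvcor_genes).astype(int),
        metcor=lambda d: d["gene"].isin(cohort.truth.metcor_genes).astype(int),
    ).to_csv(outdir / "planted_genes.tsv", sep="\t", index=False)
    normals = pd.DataFrame(cohort.truth.normal_means)
    normals.index.name = "gene"
    normals.to_csv(outdir / "normal_means.tsv", sep="\t",
                   float_format=_FLOAT_FMT)
    return outdir


class CohortBundle:
    """Cohort directory contents with the sample axis cross-checked."""

    def __init__(self, segments, met, expr_counts, expr_log, mutations,
                 clinical, annotation, gene_model, truth_labels=None,
                 normal_means=None, mismatches=None):
        self.segments = segments
        self.met = met
        self.expr_counts = expr_counts
        self.expr_log = expr_log
        self.mutations = mutations
        self.clinical = clinical
        self.annotation = annotation
        self.gene_model = gene_model
        self.truth_labels = truth_labels
        self.normal_means = normal_means
        self.mismatches = mismatches or {}


def read_cohort(indir) -> CohortBundle:
    """Read a cohort directory and report per-file sample mismatches."""
    indir = Path(indir)
    for required in ("cnv.seg", "met_beta.tsv", "expr_counts.tsv",
                     "clinical.tsv", "annotation.tsv", "genes.tsv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"cohort file missing: {indir / required}")
    segments = read_seg(indir / "cnv.seg")
    met = read_matrix(indir / "met_beta.tsv", "MET")
    expr_counts = read_matrix(indir / "expr_counts.tsv", "EXPR")
    expr_log_path = indir / "expr_log.tsv"
    expr_log = read_matrix(expr_log_path, "EXPR") if expr_log_path.exists() else None
    mutations = read_maf(indir / "mutations.maf") \
        if (indir / "mutations.maf").exists() else None
    clinical = read_clinical(indir / "clinical.tsv")
    annotation = read_annotation(indir / "annotation.tsv")
    gene_model = pd.read_csv(indir / "genes.tsv", sep="\t",
                             dtype={"chromosome": str})
    truth = None
    if (indir / "truth.tsv").exists():
        truth = pd.read_csv(indir / "truth.tsv", sep="\t",
                            index_col=0)["subtype"]
    normal_means = None
    if (indir / "normal_means.tsv").exists():
        normal_means = pd.read_csv(indir / "normal_means.tsv", sep="\t",
                                   index_col=0)

    core = set(expr_counts.sample_ids)
    mismatches = {}
    for name, ids in {
        "cnv.seg": set(segments["sample"]),
        "met_beta.tsv": set(met.sample_ids),
        "clinical.tsv": set(clinical["sample"]),
    }.items():
        extra, absent = ids - core, core - ids
        if extra or absent:
            mismatches[name] = {"extra": sorted(extra), "missing": sorted(absent)}
    return CohortBundle(segments, met, expr_counts, expr_log, mutations,
                        clinical, annotation, gene_model, truth, normal_means,
                        mismatches)
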