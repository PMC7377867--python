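"""Filtering, imputation, normalization and mapping of omic matrices.

Conventions: matrices are features x samples; genomic coordinates are
1-based inclusive (SEG convention); log2 ratios use a pseudocount of 1 by
default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import SEX_CHROMOSOMES, OmicsMatrix

log = logging.getLogger(__name__)

#: gene-region categories mapped to genes by default (promoter-associated)
DEFAULT_GENE_REGIONS = frozenset({"Promoter", "5'UTR", "FirstExon"})
#: CpG-island-associated categories mapped to genes by default
DEFAULT_CPG_REGIONS = frozenset({"Island", "Shore", "Shelf"})


def filter_probes(
    m: OmicsMatrix,
    max_missing_frac: float = 0.30,
    drop_sex: bool = False,
    annotation: pd.DataFrame | None = None,
) -> OmicsMatrix:
    """Drop features with a missing fraction above ``max_missing_frac`` and,
    optionally, features located on sex chromosomes.

    The default threshold 0.30 is the per-probe rule for methylation arrays;
    0.50 is used for the cross-assay matched matrix (see pipeline config).
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    missing_frac = m.values.isna().mean(axis=1)
    keep = missing_frac <= max_missing_frac
    if drop_sex:
        if annotation is None:
            raise ValueError("drop_sex requires a probe annotation")
        chrom = annotation.set_index("probe_id")["chromosome"]
        on_sex = m.feature_ids.map(chrom).isin(SEX_CHROMOSOMES)
        keep &= ~np.asarray(on_sex)
    if not keep.any():
        raise ValueError(
            f"no features retained at missing-fraction threshold {max_missing_frac}")
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_probes: dropped %d of %d features", dropped, len(keep))
    return m.copy_with(m.values.loc[keep])


def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing entries from the ``k`` nearest features.

    A missing value for feature f in sample s is replaced by the
    distance-weighted mean of the k nearest features (Euclidean distance over
    the samples both features observe) that observe s. Observed entries are
    unchanged; imputation is idempotent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.values.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return m.copy_with(m.values.copy())
    fully_missing = np.isnan(values).all(axis=1)
    if fully_missing.any():
        bad = list(m.feature_ids[fully_missing][:5])
        raise ValueError(f"features with no observed values cannot be imputed: {bad}")
    n_complete_features = (~np.isnan(values).any(axis=1)).sum()
    if n_complete_features < k:
        raise ValueError(
            f"k={k} exceeds the {n_complete_features} fully observed features")
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    # KNNImputer treats rows as observations: rows are features here, so
    # neighbors are features, as required.
    imputed = imputer.fit_transform(values)
    out = pd.DataFrame(imputed, index=m.feature_ids, columns=m.sample_ids)
    if m.assay == "MET":
        out = out.clip(0.0, 1.0)
    return m.copy_with(out)


def normalize_to_normal(
    m: OmicsMatrix,
    normal_means: pd.Series,
    pseudocount: float = 1.0,
) -> OmicsMatrix:
    """Express tumor values relative to a normal-tissue baseline.

    EXPR becomes ``log2((tumor + pc) / (baseline + pc))`` (fold change vs
    normal); MET and CNV become ``tumor - baseline``.
    """
    baseline = normal_means.reindex(m.feature_ids)
    if baseline.isna().any():
        missing = list(m.feature_ids[baseline.isna()][:5])
        raise ValueError(f"no normal baseline for features: {missing}")
    if m.assay == "EXPR":
        if pseudocount <= 0 and (baseline <= 0).any():
            raise ValueError("baseline <= 0 requires a positive pseudocount")
        if (baseline <= 0).any():
            log.warning("normalize_to_normal: %d features have baseline <= 0; "
                        "pseudocount %g keeps ratios finite",
                        int((baseline <= 0).sum()), pseudocount)
        out = np.log2(m.values.add(pseudocount, axis=0)).sub(
            np.log2(baseline + pseudocount), axis=0)
        return OmicsMatrix(out, "EXPR")
    return m.copy_with(m.values.sub(baseline, axis=0))


def map_segments_to_genes(
    segments: pd.DataFrame,
    gene_model: pd.DataFrame,
) -> OmicsMatrix:
    """Collapse segmented copy number to gene level.

    Per gene and sample, the value is the overlap-length-weighted mean of the
    means of all overlapping segments; genes with no overlapping segment are
    missing. Coordinates are 1-based inclusive in both inputs.
    """
    for col in ("sample", "chromosome", "start", "end", "seg_mean"):
        if col not in segments.columns:
            raise ValueError(f"segments missing column {col!r}")
    if (segments["start"] > segments["end"]).any() or (segments["start"] < 0).any():
        raise ValueError("malformed segment intervals")
    if (gene_model["start"] > gene_model["end"]).any():
        raise ValueError("malformed gene intervals")

    samples = pd.unique(segments["sample"])
    genes = gene_model["gene"].to_numpy()
    out = np.full((len(genes), len(samples)), np.nan)
    sample_pos = {s: j for j, s in enumerate(samples)}

    for chrom, gsub in gene_model.groupby("chromosome", sort=False):
        ssub = segments[segments["chromosome"] == chrom]
        if ssub.empty:
            continue
        g_start = gsub["start"].to_numpy()
        g_end = gsub["end"].to_numpy()
        g_rows = gsub.index.to_numpy()
        for sample, seg_s in ssub.groupby("sample", sort=False):
            s_start = seg_s["start"].to_numpy()
            s_end = seg_s["end"].to_numpy()
            s_mean = seg_s["seg_mean"].to_numpy(dtype=float)
            # pairwise overlap lengths (genes x segments); fine at toy scale
            ov = (np.minimum(g_end[:, None], s_end[None, :])
                  - np.maximum(g_start[:, None], s_start[None, :]) + 1)
            ov = np.clip(ov, 0, None).astype(float)
            total = ov.sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals = (ov @ s_mean) / total
            j = sample_pos[sample]
            hit = total > 0
            out[g_rows[hit], j] = vals[hit]
    df = pd.DataFrame(out, index=pd.Index(genes, name="gene"), columns=samples)
    return OmicsMatrix(df, "CNV")


def map_probes_to_genes(
    met: OmicsMatrix,
    annotation: pd.DataFrame,
    gene_regions: frozenset | set = DEFAULT_GENE_REGIONS,
    cpg_regions: frozenset | set = DEFAULT_CPG_REGIONS,
) -> list[tuple[str, str]]:
    """Pair methylation probes with genes.

    Only probes annotated to an allowed gene region (promoter-associated by
    default, where the promoter spans the 2500 bases upstream of the TSS) and
    an allowed CpG category are paired; sex-chromosome probes and probes with
    no gene are dropped. A probe pairs with at most one gene.
    """
    ann = annotation.set_index("probe_id")
    missing = met.feature_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation does not cover probes: {list(missing[:5])}")
    ann = ann.loc[met.feature_ids]
    ok = (
        ann["gene_region"].isin(gene_regions)
        & ann["cpg_region"].isin(cpg_regions)
        & (ann["gene"] != "")
        & ~ann["chromosome"].isin(SEX_CHROMOSOMES)
    )
    dropped = int((~ok).sum())
    if dropped:
        log.info("map_probes_to_genes: %d probes left unpaired", dropped)
    return list(zip(ann.index[ok], ann.loc[ok, "gene"]))


def quantile_log_normalize(expr: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Quantile-normalize samples on the log2 scale.

    After the transform every sample holds the same sorted value vector: the
    across-sample mean of the per-rank log2 values (ties receive the mean of
    their tied ranks' values).
    """
    vals = expr.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix")
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    logv = np.log2(vals + pseudocount)
    order = np.argsort(logv, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(logv.shape[0])[:, None], axis=0)
    mean_quantiles = np.take_along_axis(logv, order, axis=0).mean(axis=1)
    out = mean_quantiles[ranks]
    # average tied values so equal inputs map to equal outputs within a sample
    df = pd.DataFrame(out, index=expr.feature_ids, columns=expr.sample_ids)
    for j, col in enumerate(df.columns):
        tied = pd.Series(logv[:, j]).duplicated(keep=False)
        if tied.any():
            grouped = df[col].groupby(logv[:, j]).transform("mean")
            df[col] = grouped
    return OmicsMatrix(df, "EXPR")
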