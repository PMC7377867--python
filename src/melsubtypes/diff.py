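"""Between-subtype molecular comparisons.

Contains the exact tests on categorical state matrices, the mutation
frequency screen, a negative-binomial Wald differential-expression procedure
(a documented stand-in for count-based DE packages: median-of-ratios size
factors, method-of-moments dispersion, Wald test on the group log2 fold
change), subtype-overlap contingency tests, BH multiple-testing control and
the three-way concordant-gene intersection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, StateMatrix

log = logging.getLogger(__name__)

#: variant classes treated as synonymous and removed before mutation analysis
SYNONYMOUS_CLASSES = frozenset({"Silent", "Synonymous_Variant"})
#: variant classes that count as mutations (nonsense and missense)
DEFAULT_INCLUDED_CLASSES = frozenset({"Missense_Mutation", "Nonsense_Mutation"})


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability
    (with the customary 1 + 1e-7 relative tie tolerance).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return 1.0 if p > 1 - 1e-12 else p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_masks(labels: pd.Series, group_a, group_b, columns):
    labels = labels.reindex(columns)
    in_a = (labels == group_a).to_numpy()
    in_b = (labels == group_b).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"empty group: {group_a if in_a.sum() == 0 else group_b}")
    return in_a, in_b


def state_enrichment_test(
    states: StateMatrix,
    labels: pd.Series,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Per-gene, per-direction Fisher exact comparison of abnormal-state
    frequencies between two groups.

    Each abnormal state in the matrix vocabulary (e.g. Gain and Loss, or
    Hyper and Hypo) is collapsed to an abnormal-vs-not 2x2 table against
    group membership; BH adjustment runs across genes within each direction.
    """
    vals = states.values
    in_a, in_b = _group_masks(labels, group_a, group_b, vals.columns)
    directions = [s for s in states.vocabulary if s != "Normal"]
    out = []
    for direction in directions:
        is_state = (vals == direction).to_numpy()
        observed = vals.notna().to_numpy()
        a_state = (is_state & in_a).sum(axis=1)
        a_tot = (observed & in_a).sum(axis=1)
        b_state = (is_state & in_b).sum(axis=1)
        b_tot = (observed & in_b).sum(axis=1)
        pvals = np.array([
            fisher_exact_2x2([[sa, ta - sa], [sb, tb - sb]])
            if ta + tb > 0 else np.nan
            for sa, ta, sb, tb in zip(a_state, a_tot, b_state, b_tot)])
        sub = pd.DataFrame({
            "feature": vals.index,
            "direction": direction,
            "freq_a": np.divide(a_state, a_tot, out=np.zeros(len(vals)),
                                where=a_tot > 0),
            "freq_b": np.divide(b_state, b_tot, out=np.zeros(len(vals)),
                                where=b_tot > 0),
            "p": pvals,
        })
        ok = ~sub["p"].isna()
        sub.loc[ok, "q"] = bh_adjust(sub.loc[ok, "p"].to_numpy())
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc.mean(axis=1)  # log geometric mean per gene
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; cannot size-factor")
    ratios = logc[usable] - ref[usable, None]
    return np.exp(np.median(ratios, axis=0))


def differential_expression(
    counts: OmicsMatrix,
    labels: pd.Series,
    group_a,
    group_b,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression between two groups.

    Library sizes are normalized with median-of-ratios size factors; a
    per-gene dispersion is estimated by the method of moments on normalized
    counts (pooled within groups, floored at ``min_dispersion``); the Wald
    statistic tests the group log2 fold change from the per-group NB means.
    All-zero genes are excluded and reported via the ``excluded`` attr.
    """
    vals = counts.values.to_numpy(dtype=float)
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be non-negative integers")
    in_a, in_b = _group_masks(labels, group_a, group_b, counts.sample_ids)
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    use = in_a | in_b
    sub = vals[:, use]
    in_a_s, in_b_s = in_a[use], in_b[use]
    nonzero = sub.sum(axis=1) > 0
    excluded = list(counts.feature_ids[~nonzero])
    if excluded:
        log.info("differential_expression: %d all-zero genes excluded",
                 len(excluded))
    sub = sub[nonzero]
    sf = _size_factors(sub)
    norm = sub / sf[None, :]

    def group_stats(mask):
        x = norm[:, mask]
        return x.mean(axis=1), x.var(axis=1, ddof=1), mask.sum()

    mu_a, var_a, n_a = group_stats(in_a_s)
    mu_b, var_b, n_b = group_stats(in_b_s)
    # method-of-moments dispersion pooled across groups: var = mu + alpha mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a) / mu_a**2
        alpha_b = (var_b - mu_b) / mu_b**2
    alpha = np.nanmean(np.vstack([alpha_a, alpha_b]), axis=0)
    alpha = np.clip(np.nan_to_num(alpha, nan=min_dispersion),
                    min_dispersion, None)

    eps = 0.5  # pseudo-mean keeps zero-group fold changes finite
    lfc = np.log2((mu_a + eps) / (mu_b + eps))
    # Wald SE of log2 mean difference under NB: Var(log mu_hat) ~
    # (1/mu + alpha) / n per group, delta method on log2
    var_log_a = (1.0 / np.maximum(mu_a, eps) + alpha) / n_a
    var_log_b = (1.0 / np.maximum(mu_b, eps) + alpha) / n_b
    se = np.sqrt(var_log_a + var_log_b) / np.log(2)
    wald = lfc / se
    p = 2 * stats.norm.sf(np.abs(wald))
    out = pd.DataFrame({
        "feature": counts.feature_ids[nonzero],
        "base_mean": (mu_a * n_a + mu_b * n_b) / (n_a + n_b),
        "log2_fold_change": lfc,
        "dispersion": alpha,
        "stat": wald,
        "p": p,
        "q": bh_adjust(p),
    })
    out.attrs["excluded"] = excluded
    return out.reset_index(drop=True)


def maf_to_mutation_matrix(
    maf: pd.DataFrame,
    samples=None,
    included_classes=DEFAULT_INCLUDED_CLASSES,
) -> pd.DataFrame:
    """Collapse a minimal MAF to a binary gene x sample indicator.

    Synonymous-classified variants ("Silent") never contribute; only
    ``included_classes`` (nonsense and missense by default) count.
    """
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if col not in maf.columns:
            raise ValueError(f"MAF missing column {col!r}")
    kept = maf[~maf["Variant_Classification"].isin(SYNONYMOUS_CLASSES)]
    kept = kept[kept["Variant_Classification"].isin(included_classes)]
    mat = pd.crosstab(kept["Hugo_Symbol"], kept["Tumor_Sample_Barcode"])
    mat = (mat > 0).astype(int)
    if samples is not None:
        mat = mat.reindex(columns=samples, fill_value=0)
    mat.index.name = "gene"
    return mat


def mutation_frequency_test(
    mutations: pd.DataFrame,
    labels: pd.Series,
    group_a,
    group_b,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutated-vs-not frequencies between two
    groups; ``passed`` marks p < alpha (0.01 by default)."""
    in_a, in_b = _group_masks(labels, group_a, group_b, mutations.columns)
    vals = mutations.to_numpy()
    rows = []
    for gi, gene in enumerate(mutations.index):
        ma, mb = int(vals[gi, in_a].sum()), int(vals[gi, in_b].sum())
        na, nb = int(in_a.sum()), int(in_b.sum())
        p = fisher_exact_2x2([[ma, na - ma], [mb, nb - mb]])
        rows.append((gene, ma / na, mb / nb, p))
    out = pd.DataFrame(rows, columns=["gene", "freq_a", "freq_b", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["passed"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def chi_square_contingency(labels_a: pd.Series, labels_b: pd.Series):
    """Pearson chi-square on the cross-tabulation of two labelings of the
    same samples; returns (chi2, df, p, expected-counts table)."""
    a, b = labels_a.align(labels_b, join="inner")
    if len(a) == 0:
        raise ValueError("labelings share no samples")
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("each labeling needs >= 2 levels")
    table = pd.crosstab(a, b)
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        log.warning("chi_square_contingency: %d expected cells < 5",
                    int((expected < 5).sum()))
    return float(chi2), int(df), float(p), pd.DataFrame(
        expected, index=table.index, columns=table.columns)


def concordant_genes(
    met_diff: pd.DataFrame,
    cnv_diff: pd.DataFrame,
    de: pd.DataFrame,
    alpha: float = 0.05,
    direction_rule: tuple | None = ("Hyper", "down"),
) -> list:
    """Genes significant in the methylation, copy-number and expression
    comparisons simultaneously.

    ``direction_rule = (met_direction, expr_direction)`` optionally restricts
    to e.g. hypermethylated-and-downregulated genes ("Hyper", "down", where
    "down" means log2 fold change < 0 for group A vs B). Ordering is
    deterministic: ascending combined rank of the three p-values.
    """
    def significant(df, direction=None):
        sub = df[df["q"] < alpha] if "q" in df else df[df["p"] < alpha]
        if direction is not None and "direction" in sub.columns:
            sub = sub[(sub["direction"] == direction)
                      & (sub["freq_a"] > sub["freq_b"])]
        return sub

    met_dir = direction_rule[0] if direction_rule else None
    met_sig = significant(met_diff, met_dir)
    cnv_sig = significant(cnv_diff)
    de_sig = de[de["q"] < alpha]
    if direction_rule and direction_rule[1] == "down":
        de_sig = de_sig[de_sig["log2_fold_change"] < 0]
    elif direction_rule and direction_rule[1] == "up":
        de_sig = de_sig[de_sig["log2_fold_change"] > 0]

    met_genes = set(met_sig["feature"])
    cnv_genes = set(cnv_sig["feature"])
    de_genes = set(de_sig["feature"])
    common = met_genes & cnv_genes & de_genes
    if not common:
        return []

    def best_p(df, key):
        return df.groupby(key)["p"].min()

    rank = (best_p(met_diff, "feature").rank()
            .add(best_p(cnv_diff, "feature").rank(), fill_value=0)
            .add(best_p(de, "feature").rank(), fill_value=0))
    return sorted(common, key=lambda g: (rank.get(g, np.inf), g))
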