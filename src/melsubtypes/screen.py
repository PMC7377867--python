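"""Correlation screen: CNV->expression and methylation->expression.

Per gene (CNV) or probe-gene pair (MET), a Pearson correlation with
expression is computed across samples, variance-stabilized with Fisher's
z-transformation, and summarized: the CNV z-distribution is expected to be
right-skewed (dosage drives expression up) and the MET z-distribution
left-skewed (promoter methylation represses). Gene sets are then selected by
a BH-adjusted sign-constrained rule plus an overall-survival log-rank filter
on expression tertiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .survival import log_rank_test, tertile_groups

log = logging.getLogger(__name__)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) on pairwise-complete
    observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_z(r):
    """Fisher variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _corr_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r via the t distribution on n-2 df."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), n - 2)


def correlate_assay_with_expression(
    omic: OmicsMatrix,
    expr: OmicsMatrix,
    pairing: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Correlate omic features with expression across shared samples.

    ``pairing`` lists (feature, gene) pairs — probe-to-gene for MET; when
    omitted, features are matched to expression rows by identical ids (the
    CNV case). Returns one CorrelationRecord row per pairable feature:
    columns gene, probe, assay, r, z, p, n.
    """
    shared = omic.sample_ids.intersection(expr.sample_ids)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    if pairing is None:
        feats = omic.feature_ids.intersection(expr.feature_ids)
        pairing = [(f, f) for f in feats]
    pairing = [(f, g) for f, g in pairing
               if f in omic.values.index and g in expr.values.index]
    if not pairing:
        raise ValueError("no pairable features")
    feat_ids = [f for f, _ in pairing]
    gene_ids = [g for _, g in pairing]
    a = omic.values.loc[feat_ids, shared].to_numpy(dtype=float)
    b = expr.values.loc[gene_ids, shared].to_numpy(dtype=float)

    valid = ~(np.isnan(a) | np.isnan(b))
    n_pair = valid.sum(axis=1)
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        am = a.sum(axis=1) / n_pair
        bm = b.sum(axis=1) / n_pair
        ac = np.where(valid, a - am[:, None], 0.0)
        bc = np.where(valid, b - bm[:, None], 0.0)
        cov = (ac * bc).sum(axis=1)
        denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    bad = ~np.isfinite(r) | (n_pair < 3)
    if bad.any():
        log.info("correlate_assay_with_expression: %d undefined correlations "
                 "dropped", int(bad.sum()))
    rec = pd.DataFrame({
        "gene": gene_ids,
        "probe": feat_ids,
        "assay": omic.assay,
        "r": r,
        "n": n_pair,
    })[~bad].reset_index(drop=True)
    rec["z"] = np.arctanh(np.clip(rec["r"], -1 + 1e-15, 1 - 1e-15))
    rec["p"] = _corr_p(rec["r"].to_numpy(), rec["n"].to_numpy())
    return rec[["gene", "probe", "assay", "r", "z", "p", "n"]]


def select_representative_probe(records: pd.DataFrame, rule: str = "extreme") -> pd.DataFrame:
    """Collapse multi-probe genes to one record per gene.

    rule="extreme": keep the probe with the most negative r (methylation
    convention). rule="mean": synthesize a record whose r is the mean of the
    gene's probes' r (copy-number convention), with z and p recomputed.
    """
    if records.empty:
        raise ValueError("no correlation records")
    if rule not in {"extreme", "mean"}:
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "extreme":
        idx = records.groupby("gene")["r"].idxmin()
        out = records.loc[idx].copy()
    else:
        grouped = records.groupby("gene").agg(
            r=("r", "mean"), n=("n", "min"), assay=("assay", "first"))
        out = grouped.reset_index()
        out["probe"] = "(mean)"
        out["z"] = np.arctanh(np.clip(out["r"], -1 + 1e-15, 1 - 1e-15))
        out["p"] = _corr_p(out["r"].to_numpy(), out["n"].to_numpy(dtype=float))
    out["rule"] = rule
    return out.sort_values("gene").reset_index(drop=True)[
        ["gene", "probe", "assay", "r", "z", "p", "n", "rule"]]


def skewness_test(values) -> tuple[float, float]:
    """Adjusted Fisher-Pearson sample skewness plus the two-sided D'Agostino
    skewness normality test; requires n >= 8."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 8:
        raise ValueError("skewness test requires n >= 8")
    g = float(stats.skew(values, bias=False))
    stat, p = stats.skewtest(values)
    return g, float(p)


@dataclass
class CorGeneSets:
    """Selected correlated gene sets; overlap = cnvcor intersect metcor."""

    cnvcor: list
    metcor: list
    overlap: list = field(default=None)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cnvcor = sorted(self.cnvcor)
        self.metcor = sorted(self.metcor)
        self.overlap = sorted(set(self.cnvcor) & set(self.metcor))


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def select_cor_genes(
    cnv_records: pd.DataFrame,
    met_records: pd.DataFrame,
    survival: pd.DataFrame | None,
    expr: OmicsMatrix,
    q_alpha: float = 0.05,
    os_alpha: float = 0.05,
    apply_os_filter: bool = True,
) -> CorGeneSets:
    """Select CNV-correlated and MET-correlated gene sets.

    A gene is a CNVcor candidate when its representative CNV record has
    BH-adjusted correlation p < ``q_alpha`` and r > 0; METcor candidates need
    q < ``q_alpha`` and r < 0. Candidates must additionally show an
    overall-survival association: expression tertiles (L1/L2/L3) compared by
    log-rank at ``os_alpha`` (disable with ``apply_os_filter=False``).
    """
    if apply_os_filter and (survival is None or survival.empty):
        raise ValueError("survival table required for the OS filter")

    def candidates(records: pd.DataFrame, positive: bool) -> list:
        rec = records.copy()
        rec["q"] = _bh(rec["p"].to_numpy())
        sign_ok = rec["r"] > 0 if positive else rec["r"] < 0
        return list(rec.loc[(rec["q"] < q_alpha) & sign_ok, "gene"])

    cnv_cand = candidates(cnv_records, positive=True)
    met_cand = candidates(met_records, positive=False)

    if apply_os_filter:
        surv = survival.set_index("sample")
        shared = expr.sample_ids.intersection(surv.index)
        surv = surv.loc[shared]

        def os_pass(genes: list) -> list:
            kept = []
            for g in genes:
                if g not in expr.values.index:
                    continue
                vals = expr.values.loc[g, shared]
                groups = tertile_groups(vals)
                if groups.nunique() < 2:
                    continue
                _, _, p = log_rank_test(surv["os_time"], surv["os_event"], groups)
                if p < os_alpha:
                    kept.append(g)
            return kept

        cnv_cand = os_pass(cnv_cand)
        met_cand = os_pass(met_cand)

    return CorGeneSets(
        cnvcor=cnv_cand,
        metcor=met_cand,
        thresholds={"q_alpha": q_alpha, "os_alpha": os_alpha,
                    "os_filter": apply_os_filter},
    )


def arm_frequency(genes, gene_arms: pd.Series, universe) -> pd.Series:
    """Per-chromosome-arm fraction of universe genes that were selected."""
    universe = pd.Index(universe)
    arms = gene_arms.reindex(universe)
    if arms.isna().any():
        raise ValueError("every universe gene needs an arm assignment")
    selected = pd.Index(genes)
    out = {}
    for arm, members in arms.groupby(arms):
        total = len(members)
        if total == 0:  # pragma: no cover - groupby never yields empty
            log.info("arm %s has no universe genes; omitted", arm)
            continue
        out[arm] = len(selected.intersection(members.index)) / total
    return pd.Series(out, name="frequency").sort_index()


def cpg_category_tally(
    probes, annotation: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Tally selected probes by CpG category and by gene-region category."""
    ann = annotation.set_index("probe_id")
    missing = pd.Index(probes).difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation does not cover probes: {list(missing[:5])}")
    sub = ann.loc[pd.Index(probes)]
    by_cpg = sub["cpg_region"].value_counts().sort_index()
    by_region = sub["gene_region"].value_counts().sort_index()
    return by_cpg, by_region
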