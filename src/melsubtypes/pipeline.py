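"""End-to-end orchestration: cohort directory -> subtype labels and reports.

Stage order follows the analysis narrative: preprocess -> correlation screen
-> NMF subtyping -> integrative clustering -> survival -> burden linkage ->
differential features. Each stage writes its tables under the output
directory (with the config hash in a header comment) and the run ends with
a manifest of stage row counts and file checksums; identical config and seed
give identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff, icluster, nmf, preprocess, screen, states, survival
from .containers import OmicsMatrix
from .io import read_cohort

log = logging.getLogger(__name__)

STAGES = ("preprocess", "screen", "nmf", "icluster", "survival", "linkage",
          "diff")


@dataclass
class PipelineConfig:
    cohort_dir: str
    out_dir: str
    met_max_missing: float = 0.30
    matched_max_missing: float = 0.50
    knn_k: int = 10
    q_alpha: float = 0.05
    os_alpha: float = 0.05
    apply_os_filter: bool = True
    k_min: int = 2
    k_max: int = 6
    nmf_runs: int = 20
    nmf_max_iter: int = 2000
    icluster_K_candidates: tuple = (2, 3)
    icluster_restarts: int = 20
    icluster_lambda: float = 0.05
    expr_top_var: int = 100
    cnv_loss_cut: float = -0.3
    cnv_gain_cut: float = 0.3
    met_hypo_cut: float = 0.2
    met_hyper_cut: float = 0.8
    diff_alpha: float = 0.05
    mutation_alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.cohort_dir).is_dir():
            raise FileNotFoundError(f"cohort directory {self.cohort_dir}")
        for name in ("met_max_missing", "matched_max_missing"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.cnv_loss_cut >= self.cnv_gain_cut:
            raise ValueError("cnv_loss_cut must be below cnv_gain_cut")
        if self.met_hypo_cut >= self.met_hyper_cut:
            raise ValueError("met_hypo_cut must be below met_hyper_cut")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.icluster_K_candidates, list):
            cfg.icluster_K_candidates = tuple(cfg.icluster_K_candidates)
        return cfg

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # analysis parameters only, not the destination
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest = {"config": dataclasses.asdict(config), "config_hash": cfg_hash,
                "seed": config.seed, "stages": {}}
    state: dict = {}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(STAGES, ss.spawn(len(STAGES)))}

    for name in STAGES:
        t0 = time.monotonic()
        try:
            rows = _STAGE_FUNCS[name](config, state, out, cfg_hash,
                                      stage_seeds[name])
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "completed",
            "rows": rows,
            "seconds": round(time.monotonic() - t0, 2),
        }
        log.info("stage %s completed in %.1fs", name,
                 manifest["stages"][name]["seconds"])

    manifest["checksums"] = {
        p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_preprocess(config, state, out, cfg_hash, seed):
    bundle = read_cohort(config.cohort_dir)
    state["bundle"] = bundle
    met = preprocess.filter_probes(bundle.met, config.met_max_missing,
                                   drop_sex=True, annotation=bundle.annotation)
    met = preprocess.knn_impute(met, k=config.knn_k)
    cnv = preprocess.map_segments_to_genes(bundle.segments, bundle.gene_model)
    if bundle.expr_log is not None:
        expr = bundle.expr_log
    else:
        expr = preprocess.quantile_log_normalize(bundle.expr_counts)
    state["met"], state["cnv"], state["expr"] = met, cnv, expr
    state["clinical"] = bundle.clinical
    return {"met_probes": met.values.shape[0], "cnv_genes": cnv.values.shape[0],
            "expr_genes": expr.values.shape[0],
            "samples": expr.values.shape[1],
            "sample_mismatches": {k: {kk: len(vv) for kk, vv in v.items()}
                                  for k, v in bundle.mismatches.items()}}


def _stage_screen(config, state, out, cfg_hash, seed):
    pairing = preprocess.map_probes_to_genes(state["met"],
                                             state["bundle"].annotation)
    cnv_rec = screen.correlate_assay_with_expression(state["cnv"], state["expr"])
    met_rec = screen.correlate_assay_with_expression(state["met"], state["expr"],
                                                     pairing)
    cnv_rep = screen.select_representative_probe(cnv_rec, rule="mean")
    met_rep = screen.select_representative_probe(met_rec, rule="extreme")
    skew_cnv = screen.skewness_test(cnv_rep["z"])
    skew_met = screen.skewness_test(met_rep["z"])
    sets = screen.select_cor_genes(
        cnv_rep, met_rep, state["clinical"], state["expr"],
        q_alpha=config.q_alpha, os_alpha=config.os_alpha,
        apply_os_filter=config.apply_os_filter)
    # gene-level beta matrix from the representative (most-negative-r) probes
    rep_probes = met_rep.set_index("gene")["probe"]
    met_gene = state["met"].values.loc[rep_probes.to_numpy()]
    met_gene.index = rep_probes.index
    state["met_gene"] = OmicsMatrix(met_gene, "MET")
    state["records"] = {"CNV": cnv_rep, "MET": met_rep}
    state["sets"] = sets
    state["skewness"] = {"CNV": skew_cnv, "MET": skew_met}
    _write(cnv_rep, out / "screen_cnv_records.tsv", cfg_hash, index=False)
    _write(met_rep, out / "screen_met_records.tsv", cfg_hash, index=False)
    gene_arms = state["bundle"].gene_model.set_index("gene")["arm"]
    arm_cnv = screen.arm_frequency(sets.cnvcor, gene_arms, gene_arms.index)
    arm_met = screen.arm_frequency(sets.metcor, gene_arms, gene_arms.index)
    _write(pd.DataFrame({"cnvcor": arm_cnv, "metcor": arm_met}).fillna(0.0),
           out / "screen_arm_frequency.tsv", cfg_hash)
    met_probes = met_rep[met_rep["gene"].isin(sets.metcor)]["probe"]
    if len(met_probes):
        by_cpg, by_region = screen.cpg_category_tally(
            met_probes, state["bundle"].annotation)
        _write(pd.DataFrame({"count": by_cpg}), out / "screen_cpg_tally.tsv",
               cfg_hash)
        _write(pd.DataFrame({"count": by_region}),
               out / "screen_gene_region_tally.tsv", cfg_hash)
    _write(pd.DataFrame({
        "set": ["cnvcor", "metcor", "overlap"],
        "n_genes": [len(sets.cnvcor), len(sets.metcor), len(sets.overlap)],
        "genes": [";".join(sets.cnvcor), ";".join(sets.metcor),
                  ";".join(sets.overlap)],
    }), out / "screen_gene_sets.tsv", cfg_hash, index=False)
    return {"cnv_records": len(cnv_rep), "met_records": len(met_rep),
            "cnvcor": len(sets.cnvcor), "metcor": len(sets.metcor),
            "overlap": len(sets.overlap),
            "skew_cnv_z": round(skew_cnv[0], 4),
            "skew_met_z": round(skew_met[0], 4)}


def _nmf_input(state, which):
    sets = state["sets"]
    if which == "CNV":
        genes = [g for g in sets.cnvcor if g in state["cnv"].values.index]
        return nmf.nonnegative_transform(state["cnv"].values.loc[genes])
    genes = [g for g in sets.metcor if g in state["met_gene"].values.index]
    return state["met_gene"].values.loc[genes]


def _stage_nmf(config, state, out, cfg_hash, seed):
    results = {}
    for i, which in enumerate(("CNV", "MET")):
        V = _nmf_input(state, which)
        if V.shape[0] < config.k_max + 1:
            raise ValueError(f"too few {which} features for NMF rank search")
        k_star, diag, per_k = nmf.select_rank(
            V, k_min=config.k_min, k_max=config.k_max, n_runs=config.nmf_runs,
            seed=seed + i, max_iter=config.nmf_max_iter)
        res = per_k[k_star]
        results[which] = res
        _write(diag, out / f"nmf_{which.lower()}_rank_diagnostics.tsv",
               cfg_hash, index=False)
        _write(res.labels.to_frame(), out / f"nmf_{which.lower()}_labels.tsv",
               cfg_hash)
        _write(res.consensus, out / f"nmf_{which.lower()}_consensus.tsv",
               cfg_hash)
    state["nmf"] = results
    chi2, df, p, _ = diff.chi_square_contingency(results["CNV"].labels,
                                                 results["MET"].labels)
    _write(pd.DataFrame({"chi2": [chi2], "df": [df], "p": [p]}),
           out / "nmf_overlap_test.tsv", cfg_hash, index=False)
    state["nmf_overlap_p"] = p
    return {"k_cnv": results["CNV"].k, "k_met": results["MET"].k,
            "overlap_p": p}


def _stage_icluster(config, state, out, cfg_hash, seed):
    sets = state["sets"]
    cnv = icluster.standardize_features(
        state["cnv"].values.loc[[g for g in sets.cnvcor
                                 if g in state["cnv"].values.index]])
    met = icluster.standardize_features(
        state["met_gene"].values.loc[[g for g in sets.metcor
                                      if g in state["met_gene"].values.index]])
    expr_all = state["expr"].values
    top = expr_all.var(axis=1).nlargest(config.expr_top_var).index
    expr = icluster.standardize_features(expr_all.loc[top])
    datasets = [cnv, met, expr]
    K_star, stability = icluster.choose_K(
        datasets, K_candidates=config.icluster_K_candidates,
        lam=config.icluster_lambda, n_restarts=config.icluster_restarts,
        seed=seed)
    model = icluster.icluster_fit(
        datasets, K=K_star, lam=config.icluster_lambda,
        n_restarts=config.icluster_restarts, seed=seed + 1)
    state["icluster"] = model
    _write(stability, out / "icluster_stability.tsv", cfg_hash, index=False)
    _write(model.labels.to_frame(), out / "icluster_labels.tsv", cfg_hash)
    summary = {"K": model.K, "lambda": model.lambdas,
               "loglik": model.loglik, "restart": model.restart_index,
               "converged": bool(model.converged), "flags": model.flags}
    (out / "icluster_summary.json").write_text(json.dumps(summary, indent=2))
    chi2, df, p, _ = diff.chi_square_contingency(model.labels,
                                                 state["nmf"]["CNV"].labels)
    _write(pd.DataFrame({"chi2": [chi2], "df": [df], "p": [p]}),
           out / "icluster_vs_nmf_test.tsv", cfg_hash, index=False)
    return {"K": model.K, "clusters": int(model.labels.nunique()),
            "vs_nmf_p": p}


def _stage_survival(config, state, out, cfg_hash, seed):
    clin = state["clinical"].set_index("sample")
    labels = state["icluster"].labels
    shared = labels.index.intersection(clin.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between labels and clinical table")
    clin = clin.loc[shared]
    labels = labels.loc[shared]
    chi2, df, p = survival.log_rank_test(clin["os_time"], clin["os_event"],
                                         labels)
    curves = []
    for level, members in labels.groupby(labels):
        km = survival.km_estimate(clin.loc[members.index, "os_time"],
                                  clin.loc[members.index, "os_event"])
        km.insert(0, "group", level)
        curves.append(km)
    _write(pd.concat(curves, ignore_index=True), out / "km_curves.tsv",
           cfg_hash, index=False)
    _write(pd.DataFrame({"chi2": [chi2], "df": [df], "p": [p]}),
           out / "survival_logrank.tsv", cfg_hash, index=False)
    state["survival_p"] = p
    # per-subtype median KM time orders prognosis (worst vs best for diff)
    medians = {}
    for level, members in labels.groupby(labels):
        km = survival.km_estimate(clin.loc[members.index, "os_time"],
                                  clin.loc[members.index, "os_event"])
        below = km[km["survival"] <= 0.5]
        medians[level] = float(below["time"].iloc[0]) if len(below) else np.inf
    order = sorted(medians, key=lambda k: medians[k])
    state["worst_group"], state["best_group"] = order[0], order[-1]
    return {"logrank_p": p, "median_km_time": {k: (None if np.isinf(v) else v)
                                               for k, v in medians.items()},
            "worst": state["worst_group"], "best": state["best_group"]}


def _stage_linkage(config, state, out, cfg_hash, seed):
    cnv_states = states.call_cnv_states(state["cnv"], config.cnv_loss_cut,
                                        config.cnv_gain_cut)
    met_states = states.call_met_states(state["met_gene"], config.met_hypo_cut,
                                        config.met_hyper_cut)
    burden = states.sample_burden(cnv_states, met_states)
    r, p = states.burden_linkage(burden)
    coupling = states.cross_assay_burden_correlation(burden)
    state["cnv_states"], state["met_states"] = cnv_states, met_states
    _write(burden, out / "burden.tsv", cfg_hash)
    _write(r, out / "burden_linkage_r.tsv", cfg_hash)
    _write(p, out / "burden_linkage_p.tsv", cfg_hash)
    return {"samples": len(burden), "cross_assay_r": round(coupling, 4)}


def _stage_diff(config, state, out, cfg_hash, seed):
    labels = state["icluster"].labels
    worst, best = state["worst_group"], state["best_group"]
    bundle = state["bundle"]
    met_diff = diff.state_enrichment_test(state["met_states"], labels, worst,
                                          best)
    cnv_diff = diff.state_enrichment_test(state["cnv_states"], labels, worst,
                                          best)
    de = diff.differential_expression(bundle.expr_counts, labels, worst, best)
    _write(met_diff, out / "diff_met_states.tsv", cfg_hash, index=False)
    _write(cnv_diff, out / "diff_cnv_states.tsv", cfg_hash, index=False)
    _write(de, out / "diff_expression.tsv", cfg_hash, index=False)
    concordant = diff.concordant_genes(met_diff, cnv_diff, de,
                                       alpha=config.diff_alpha)
    _write(pd.DataFrame({"gene": concordant}), out / "concordant_genes.tsv",
           cfg_hash, index=False)
    # prognostic screen on the concordant genes' expression tertiles
    n_prognostic = 0
    if concordant:
        feats = OmicsMatrix(state["expr"].values.loc[concordant], "EXPR")
        prog = survival.univariate_survival_screen(feats, state["clinical"],
                                                   alpha=config.os_alpha)
        _write(prog, out / "concordant_prognostic.tsv", cfg_hash, index=False)
        n_prognostic = int(prog["passed"].sum())
    mut_rows = 0
    if bundle.mutations is not None and len(bundle.mutations):
        mat = diff.maf_to_mutation_matrix(bundle.mutations,
                                          samples=labels.index)
        mut = diff.mutation_frequency_test(mat, labels, worst, best,
                                           alpha=config.mutation_alpha)
        _write(mut, out / "diff_mutations.tsv", cfg_hash, index=False)
        mut_rows = int(mut["passed"].sum())
    return {"met_tests": len(met_diff), "cnv_tests": len(cnv_diff),
            "de_genes_q<alpha": int((de["q"] < config.diff_alpha).sum()),
            "concordant": len(concordant), "prognostic": n_prognostic,
            "mutation_hits": mut_rows}


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "screen": _stage_screen,
    "nmf": _stage_nmf,
    "icluster": _stage_icluster,
    "survival": _stage_survival,
    "linkage": _stage_linkage,
    "diff": _stage_diff,
}
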