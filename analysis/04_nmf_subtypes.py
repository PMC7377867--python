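#!/usr/bin/env python
"""Consensus NMF subtyping on the CNVcor and METcor gene sets.

Runs Brunet-style KL NMF with 20 random restarts per rank over k=2..6 on
(a) the signed copy-number matrix of CNVcor genes (split into positive and
negative parts) and (b) the representative-probe beta matrix of METcor
genes, picks each rank by cophenetic correlation, and tests how strongly the
two subtype labelings overlap. Writes diagnostics and labels to
results/04_nmf/.
"""

import argparse
from pathlib import Path

import pandas as pd

from melsubtypes import diff, nmf
from melsubtypes.io import read_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--prep", type=Path, default=Path("results/02_preprocess"))
ap.add_argument("--screen", type=Path, default=Path("results/03_screen"))
ap.add_argument("--out", type=Path, default=Path("results/04_nmf"))
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--n-runs", type=int, default=20)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cnv = read_matrix(args.prep / "cnv_gene.tsv", "CNV")
met = read_matrix(args.prep / "met_imputed.tsv", "MET")
met_rep = pd.read_csv(args.screen / "met_records.tsv", sep="\t")
results = {}
for tag, V in [
    ("cnv", nmf.nonnegative_transform(cnv.values.loc[
        pd.read_csv(args.screen / "cnvcor_genes.txt")["gene"]])),
    ("met", met.values.loc[met_rep.set_index("gene").loc[
        pd.read_csv(args.screen / "metcor_genes.txt")["gene"], "probe"]]),
]:
    k_star, diag, per_k = nmf.select_rank(V, k_min=2, k_max=6,
                                          n_runs=args.n_runs, seed=args.seed)
    res = per_k[k_star]
    results[tag] = res
    diag.to_csv(args.out / f"{tag}_rank_diagnostics.tsv", sep="\t",
                index=False)
    res.labels.to_frame().to_csv(args.out / f"{tag}_labels.tsv", sep="\t")
    res.consensus.to_csv(args.out / f"{tag}_consensus.tsv", sep="\t")
    print(f"{tag.upper()}cor features: k*={k_star} "
          f"(cophenetic {res.cophenetic:.3f}, silhouette {res.silhouette:.3f}),"
          f" cluster sizes {res.labels.value_counts().sort_index().to_dict()}")

chi2, df, p, _ = diff.chi_square_contingency(results["cnv"].labels,
                                             results["met"].labels)
pd.DataFrame({"chi2": [chi2], "df": [df], "p": [p]}).to_csv(
    args.out / "overlap_test.tsv", sep="\t", index=False)
print(f"CNVcor vs METcor subtype overlap: chi2={chi2:.1f}, df={df}, p={p:.2e}")
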