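#!/usr/bin/env python
"""Molecular differences between the worst- and best-prognosis subtypes.

Per-gene Fisher exact tests on copy-number and methylation state calls,
negative-binomial Wald differential expression on the counts, mutation-
frequency Fisher tests (synonymous variants removed, P<0.01), the
three-way concordant-gene intersection (hypermethylated + downregulated in
the worst-prognosis subtype), and a tertile log-rank prognosis screen of the
concordant genes. Writes tables to results/08_differential/.
"""

import argparse
from pathlib import Path

import pandas as pd

from melsubtypes import diff, survival
from melsubtypes.containers import OmicsMatrix
from melsubtypes.io import read_cohort
from melsubtypes.states import StateMatrix
from melsubtypes.containers import CNV_STATES, MET_STATES

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--labels", type=Path,
                default=Path("results/05_icluster/labels.tsv"))
ap.add_argument("--surv", type=Path, default=Path("results/06_survival"))
ap.add_argument("--linkage", type=Path, default=Path("results/07_linkage"))
ap.add_argument("--out", type=Path, default=Path("results/08_differential"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

bundle = read_cohort(args.cohort)
labels = pd.read_csv(args.labels, sep="\t", index_col=0)["icluster_subtype"]
logrank = pd.read_csv(args.surv / "logrank.tsv", sep="\t")
worst, best = logrank["worst"].iloc[0], logrank["best"].iloc[0]

cnv_states = StateMatrix(pd.read_csv(args.linkage / "cnv_states.tsv",
                                     sep="\t", index_col=0), CNV_STATES)
met_states = StateMatrix(pd.read_csv(args.linkage / "met_states.tsv",
                                     sep="\t", index_col=0), MET_STATES)

cnv_diff = diff.state_enrichment_test(cnv_states, labels, worst, best)
met_diff = diff.state_enrichment_test(met_states, labels, worst, best)
de = diff.differential_expression(bundle.expr_counts, labels, worst, best)
concordant = diff.concordant_genes(met_diff, cnv_diff, de, alpha=0.05,
                                   direction_rule=("Hyper", "down"))

cnv_diff.to_csv(args.out / "cnv_state_tests.tsv", sep="\t", index=False)
met_diff.to_csv(args.out / "met_state_tests.tsv", sep="\t", index=False)
de.to_csv(args.out / "expression_tests.tsv", sep="\t", index=False)
pd.Series(concordant, name="gene").to_csv(args.out / "concordant_genes.txt",
                                          index=False)

print(f"contrast: {worst} (worst prognosis) vs {best} (best)")
print(f"  CNV state tests q<0.05: {(cnv_diff['q'] < 0.05).sum()}")
print(f"  MET state tests q<0.05: {(met_diff['q'] < 0.05).sum()}")
print(f"  DE genes q<0.05: {(de['q'] < 0.05).sum()}")
print(f"  concordant (hyper + down + CNV): {len(concordant)}")

if concordant:
    feats = OmicsMatrix(bundle.expr_log.values.loc[concordant], "EXPR")
    prog = survival.univariate_survival_screen(feats, bundle.clinical,
                                               alpha=0.05)
    prog.to_csv(args.out / "concordant_prognostic.tsv", sep="\t", index=False)
    print(f"  concordant genes prognostic at log-rank p<0.05: "
          f"{int(prog['passed'].sum())}")

if bundle.mutations is not None:
    mat = diff.maf_to_mutation_matrix(bundle.mutations, samples=labels.index)
    mut = diff.mutation_frequency_test(mat, labels, worst, best, alpha=0.01)
    mut.to_csv(args.out / "mutation_tests.tsv", sep="\t", index=False)
    hits = mut[mut["passed"]]
    print(f"  differentially mutated genes (p<0.01): {len(hits)}"
          + (f" -> {list(hits['gene'])}" if len(hits) else ""))
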