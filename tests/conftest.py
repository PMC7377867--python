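import numpy as np
import pandas as pd
import pytest

from melsubtypes.containers import OmicsMatrix
from melsubtypes.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 4-subtype cohort for structural and pipeline tests."""
    cfg = SimConfig(n_samples=60, n_genes=300, n_cnvcor_genes=30,
                    n_metcor_genes=30, n_overlap_genes=10, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study's default scale (200 samples, 2000 genes)."""
    return generate_cohort(SimConfig(seed=3))


@pytest.fixture(scope="session")
def met_gene_matrix(default_cohort):
    """Gene-level beta matrix from promoter probes, planted MET genes only."""
    c = default_cohort
    ann = c.annotation
    prom = ann[(ann["gene_region"] == "Promoter")
               & ann["gene"].isin(c.truth.metcor_genes)]
    m = c.met.values.loc[prom["probe_id"].to_numpy()].copy()
    m.index = prom["gene"].to_numpy()
    m = m.apply(lambda row: row.fillna(row.mean()), axis=1)
    return OmicsMatrix(m, "MET")


def frame(values, prefix_r="f", prefix_c="s", assay="EXPR"):
    """Small OmicsMatrix helper for hand-built examples."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix_r}{i}" for i in range(values.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(values.shape[1])],
    )
    return OmicsMatrix(df, assay)
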