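"""Directional abnormality calls and per-sample burden linkage.

Copy-number gene values (fold change vs normal) are called Loss/Normal/Gain
at +-0.3 by default; methylation beta values are called Hypo/Normal/Hyper at
0.2/0.8. Per-sample burdens are the fractions of features in each abnormal
state; the linkage analysis correlates those burdens across samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CNV_STATES, MET_STATES, OmicsMatrix, StateMatrix

log = logging.getLogger(__name__)

BURDEN_COLUMNS = ("freq_gain", "freq_loss", "freq_hyper", "freq_hypo")


def call_cnv_states(
    cnv: OmicsMatrix,
    loss_cut: float = -0.3,
    gain_cut: float = 0.3,
) -> StateMatrix:
    """Call Loss/Normal/Gain per gene and sample; missing stays missing."""
    if loss_cut >= gain_cut:
        raise ValueError("loss_cut must be below gain_cut")
    vals = cnv.values.to_numpy(dtype=float)
    out = np.where(vals > gain_cut, "Gain",
                   np.where(vals < loss_cut, "Loss", "Normal")).astype(object)
    out[np.isnan(vals)] = np.nan
    return StateMatrix(
        values=pd.DataFrame(out, index=cnv.feature_ids, columns=cnv.sample_ids),
        vocabulary=CNV_STATES,
        thresholds={"loss_cut": loss_cut, "gain_cut": gain_cut},
    )


def call_met_states(
    met: OmicsMatrix,
    hypo_cut: float = 0.2,
    hyper_cut: float = 0.8,
) -> StateMatrix:
    """Call Hypo/Normal/Hyper on beta-scale values (absolute beta by default;
    pass a normal-subtracted matrix for the delta variant)."""
    if hypo_cut >= hyper_cut:
        raise ValueError("hypo_cut must be below hyper_cut")
    vals = met.values.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and (observed.min() < -1 - 1e-9 or observed.max() > 1 + 1e-9):
        raise ValueError("values outside the beta scale")
    out = np.where(vals > hyper_cut, "Hyper",
                   np.where(vals < hypo_cut, "Hypo", "Normal")).astype(object)
    out[np.isnan(vals)] = np.nan
    return StateMatrix(
        values=pd.DataFrame(out, index=met.feature_ids, columns=met.sample_ids),
        vocabulary=MET_STATES,
        thresholds={"hypo_cut": hypo_cut, "hyper_cut": hyper_cut},
    )


def sample_burden(cnv_states: StateMatrix, met_states: StateMatrix) -> pd.DataFrame:
    """Per-sample fractions of non-missing features in each abnormal state."""
    shared = cnv_states.values.columns.intersection(met_states.values.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between state matrices")

    def frac(states: StateMatrix, label: str) -> pd.Series:
        vals = states.values.loc[:, shared]
        return (vals == label).sum(axis=0) / vals.notna().sum(axis=0)

    return pd.DataFrame({
        "freq_gain": frac(cnv_states, "Gain"),
        "freq_loss": frac(cnv_states, "Loss"),
        "freq_hyper": frac(met_states, "Hyper"),
        "freq_hypo": frac(met_states, "Hypo"),
    })


def burden_linkage(burden: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p between the four burden columns.

    Constant columns yield NaN for their pairs (flagged via a log message)
    rather than an error."""
    cols = [c for c in BURDEN_COLUMNS if c in burden.columns]
    if len(burden) < 3:
        raise ValueError("burden linkage needs >= 3 samples")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = burden[a], burden[b]
            if x.std() == 0 or y.std() == 0:
                log.warning("burden_linkage: constant column in pair (%s, %s)", a, b)
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def cross_assay_burden_correlation(burden: pd.DataFrame) -> float:
    """Correlation between total CNV burden (gain + loss) and total MET
    burden (hyper + hypo) — the headline per-sample coupling estimate."""
    cnv_total = burden["freq_gain"] + burden["freq_loss"]
    met_total = burden["freq_hyper"] + burden["freq_hypo"]
    r, _ = stats.pearsonr(cnv_total, met_total)
    return float(r)
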