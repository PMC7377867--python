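"""Kaplan-Meier estimation, log-rank testing and expression tertile grouping.

Conventions: event indicator 1 = death observed, 0 = censored; at tied
times deaths are processed before censorings; log-rank p-values come from
the chi-square asymptotic distribution without continuity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from .containers import OmicsMatrix

log = logging.getLogger(__name__)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event-or-censoring time with columns
    ``time``, ``at_risk``, ``deaths``, ``censored``, ``survival``;
    ``survival`` is S(t) = prod_{t_i <= t} (1 - d_i / n_i). Times where only
    censorings occur change the at-risk count but not S.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n_at_risk = len(t)
    surv = 1.0
    rows = []
    for u in uniq:
        here = t == u
        d = int(e[here].sum())
        c = int((~e[here].astype(bool)).sum())
        if d > 0:
            surv *= 1.0 - d / n_at_risk
        rows.append((u, n_at_risk, d, c, surv))
        n_at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "at_risk", "deaths", "censored",
                                       "survival"])


def log_rank_test(times, events, groups) -> tuple[float, int, float]:
    """Log-rank test across two or more groups.

    Returns (chi2, df, p) with df = #groups - 1, from the standard
    observed-minus-expected statistic over the pooled event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    if e.sum() == 0:
        raise ValueError("log-rank test undefined with no observed events")
    res = multivariate_logrank_test(t, g, e)
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def tertile_groups(values) -> pd.Series:
    """Split values into L1 (low) / L2 / L3 (high) at the empirical 1/3 and
    2/3 quantiles; ties at a boundary all go to the lower group."""
    s = pd.Series(values)
    if len(s) < 3:
        raise ValueError("tertile grouping needs n >= 3")
    v = s.to_numpy(dtype=float)
    srt = np.sort(v)
    n = len(v)
    q1 = srt[max(0, n // 3 - 1)]
    q2 = srt[max(0, (2 * n) // 3 - 1)]
    labels = np.where(v <= q1, "L1", np.where(v <= q2, "L2", "L3"))
    out = pd.Series(labels, index=s.index, name="tertile")
    if out.nunique() == 1:
        log.warning("tertile_groups: constant values; all samples in L1")
    return out


def univariate_survival_screen(
    features: OmicsMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature tertile grouping followed by a log-rank test.

    Returns a DataFrame (feature, chi2, p, passed) sorted by p; ``passed``
    marks p < alpha.
    """
    surv = survival.set_index("sample")
    shared = features.sample_ids.intersection(surv.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    surv = surv.loc[shared]
    t = surv["os_time"].to_numpy(dtype=float)
    e = surv["os_event"].to_numpy(dtype=int)
    rows = []
    for feat in features.feature_ids:
        vals = features.values.loc[feat, shared]
        if vals.isna().any():
            continue
        groups = tertile_groups(vals)
        if groups.nunique() < 2:
            continue
        chi2, _, p = log_rank_test(t, e, groups)
        rows.append((feat, chi2, p))
    out = pd.DataFrame(rows, columns=["feature", "chi2", "p"])
    out["passed"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)
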